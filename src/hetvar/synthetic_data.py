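"""Synthetic multi-herd lactation data with known genetic truth.

Emulates the data structure a heterogeneity-of-variance (HV) evaluation
assumes: a two-generation sire/dam pedigree with breed-composition
fractions, daughters recorded over several parities in herds whose mean
production spans low- and high-variance strata, and phenotypes generated
from the repeatability animal model itself —

    y = CG + age effects + beta_dh * DH + a_stratum + p + e

with breeding values a drawn from N(0, G0 (x) A) over the pedigree
relationship matrix A (two correlated expressions of the trait, one per
stratum, correlation r_g), permanent-environment effects p per cow, and
stratum-specific residuals.  Every downstream stage therefore has a
parameter-recovery target with known truth.

What it does NOT emulate: selection/culling, genomic markers, lactation
curves, or herd-size skew; herd assignment is uniform and lactation length
is uniform on a configurable interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import pedigree as ped_mod
from .data_prep import compute_dh

BREED_PROFILES = {
    # Holstein fraction of the sires; dams vary so DH is nondegenerate
    "holstein_sire": 1.0,
    "gir_sire": 0.0,
    "girolando_sire": 0.625,
}
_DAM_FRACTIONS = np.array([0.0, 0.25, 0.375, 0.5, 0.625, 0.75, 1.0])


@dataclass
class TrueParameters:
    """Generative truth for one simulated population.

    Variances are kg^2 on the 305-day milk-yield scale; defaults follow the
    magnitudes typical of Bayesian HV analyses of Brazilian dairy herds
    (additive ~2-3k, permanent environment ~5k, residual 12-21k, herd-mean
    spread ~1200 kg, between-stratum genetic correlation 0.9).
    """

    sigma2_a_low: float = 2100.0
    sigma2_a_high: float = 3000.0
    sigma2_p: float = 5000.0
    sigma2_e_low: float = 11700.0
    sigma2_e_high: float = 21200.0
    r_g: float = 0.9
    beta_dh: float = 250.0       # kg per unit DH
    beta_age1: float = 25.0      # kg per month, centered at 60 months
    beta_age2: float = -0.35     # kg per month^2
    herd_mean_spread: float = 1200.0  # scale of herd-mean deviations, kg
    # Guard band: herd means stay at least this far from the overall mean,
    # so the realized herd-year SD classes identify the generative strata.
    # Without it, herds sitting on the boundary flip class on herd-year
    # noise and each class becomes a mixture of both residual-variance
    # strata, leaving the per-stratum truth ill-defined.
    herd_gap: float = 300.0      # kg
    base_mean: float = 5000.0    # overall MY305 level, kg
    # True |MY-on-LL slope| used to de-standardize MY305 into MY.  The
    # additive standardization MY305 = MY + b1 (LL - 305) re-applies the
    # fitted trend instead of removing it, so a slope c leaks 4 c^2 Var(LL)
    # of extra noise into the standardized trait; the default is kept small
    # so the recovery scenarios' residual truth stays interpretable.
    b1_ll: float = 0.1           # kg/day

    cg_effect_sd: float = 100.0  # herd-year-season wiggle, kg
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma2_a_low", "sigma2_a_high", "sigma2_p", "sigma2_e_low", "sigma2_e_high"):
            if getattr(self, name) < 0 or (name.startswith("sigma2_e") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if abs(self.r_g) > 1:
            raise ValueError("|r_g| must be <= 1")
        for h2 in (self.h2_low, self.h2_high):
            if not 0 <= h2 < 1:
                raise ValueError("implied h2 outside [0, 1)")

    @property
    def g0(self) -> np.ndarray:
        """2x2 additive genetic covariance across (low, high) strata."""
        c = self.r_g * np.sqrt(self.sigma2_a_low * self.sigma2_a_high)
        return np.array([[self.sigma2_a_low, c], [c, self.sigma2_a_high]])

    @property
    def h2_low(self) -> float:
        return self.sigma2_a_low / (self.sigma2_a_low + self.sigma2_p + self.sigma2_e_low)

    @property
    def h2_high(self) -> float:
        return self.sigma2_a_high / (self.sigma2_a_high + self.sigma2_p + self.sigma2_e_high)


@dataclass
class SimulatedDataset:
    pedigree: pd.DataFrame
    records: pd.DataFrame
    true_ebv: pd.DataFrame  # index animal, columns bv_low, bv_high
    truth: TrueParameters
    herd_stratum: pd.Series  # herd -> 'low'/'high' generative stratum
    n_clamped: int = 0


def simulate_pedigree(
    n_sires: int,
    n_dams: int,
    daughters_per_sire: int,
    breed_profile: str = "girolando_sire",
    seed: int = 0,
) -> pd.DataFrame:
    """Two-generation pedigree: founder sires/dams plus recorded daughters.

    Sires carry the profile's Holstein fraction; dam fractions are drawn
    from a grid so sire-by-dam DH values vary.  Daughters inherit the mean
    parental fraction.  Deterministic given the seed.
    """
    if min(n_sires, n_dams, daughters_per_sire) < 1:
        raise ValueError("counts must be >= 1")
    if breed_profile not in BREED_PROFILES:
        raise ValueError(f"unknown breed_profile {breed_profile!r}")
    rng = np.random.default_rng(seed)
    sire_frac = BREED_PROFILES[breed_profile]

    rows = []
    for i in range(n_sires):
        bd = pd.Timestamp("2005-01-01") + pd.Timedelta(days=int(rng.integers(0, 1095)))
        rows.append((i + 1, 0, 0, bd, sire_frac, 1.0 - sire_frac))
    dam_frac = rng.choice(_DAM_FRACTIONS, size=n_dams)
    for j in range(n_dams):
        bd = pd.Timestamp("2006-01-01") + pd.Timedelta(days=int(rng.integers(0, 1095)))
        rows.append((n_sires + j + 1, 0, 0, bd, dam_frac[j], 1.0 - dam_frac[j]))
    next_id = n_sires + n_dams + 1
    for i in range(n_sires):
        for _ in range(daughters_per_sire):
            dam = n_sires + 1 + int(rng.integers(0, n_dams))
            f1 = 0.5 * (sire_frac + dam_frac[dam - n_sires - 1])
            bd = pd.Timestamp("2011-06-01") + pd.Timedelta(days=int(rng.integers(0, 730)))
            rows.append((next_id, i + 1, dam, bd, f1, 1.0 - f1))
            next_id += 1
    return pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "birth_date", "frac_breed1", "frac_breed2"]
    )


def simulate_breeding_values(
    rs: ped_mod.RelationshipStructure, g0: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw (n, 2) breeding values from N(0, G0 (x) A) by pedigree recursion.

    Founders get chol(G0) z; offspring get the parent average plus Mendelian
    sampling scaled by the within-family variance d_i, which reproduces the
    G0 (x) A covariance exactly (inbreeding included via d_i).
    """
    if rs.inbreeding is None:
        ped_mod.compute_inbreeding(rs)
    n = rs.n_animals
    vals = np.linalg.eigvalsh(g0)
    if vals.min() < -1e-9:
        raise ValueError("G0 not positive semi-definite")
    L = np.linalg.cholesky(g0 + 1e-12 * np.eye(2))
    a = np.zeros((n, 2))
    z = rng.standard_normal((n, 2))
    for i in range(n):
        s, d = rs.sire_idx[i], rs.dam_idx[i]
        mean = np.zeros(2)
        if s >= 0:
            mean += 0.5 * a[s]
        if d >= 0:
            mean += 0.5 * a[d]
        dv = ped_mod._mendelian_variance(i, rs.sire_idx, rs.dam_idx, rs.inbreeding)
        a[i] = mean + np.sqrt(dv) * (L @ z[i])
    return a


def simulate_records(
    pedigree: pd.DataFrame,
    truth: TrueParameters,
    n_herds: int = 20,
    years=range(2014, 2018),
    max_parities: int = 3,
) -> SimulatedDataset:
    """Generate lactation records for every pedigree daughter.

    Each cow belongs to one herd for life; herd means are N(base_mean,
    herd_mean_spread^2), and herds at or below the base mean form the low
    generative stratum.  Each cow calves in 1..max_parities consecutive
    years.  MY is back-computed from the MY305-scale phenotype via the true
    LL slope so the data-prep standardization is exercised both ways.
    """
    if len(pedigree) == 0:
        raise ValueError("empty pedigree")
    years = list(years)
    rng = np.random.default_rng(truth.seed)

    rs = ped_mod.renumber(pedigree)
    ped_mod.compute_inbreeding(rs)
    bv = simulate_breeding_values(rs, truth.g0, rng)
    true_ebv = pd.DataFrame(bv, index=pd.Index(rs.order, name="animal"), columns=["bv_low", "bv_high"])

    # half-normal magnitudes outside the guard band, balanced signs (half
    # the herds low, half high), centered so the realized record-level mean
    # sits inside the band
    # magnitudes truncated at two spreads so even the lowest herd keeps
    # every total yield positive (herd means ~ base -/+ [gap, gap+2*spread])
    mags = truth.herd_gap + np.minimum(
        np.abs(rng.normal(0.0, truth.herd_mean_spread, n_herds)), 2.0 * truth.herd_mean_spread
    )
    signs = np.ones(n_herds)
    signs[: n_herds // 2] = -1.0
    rng.shuffle(signs)
    herd_dev = mags * signs
    herd_dev -= herd_dev.mean()
    stratum = np.where(herd_dev <= 0, "low", "high")
    herd_stratum = pd.Series(stratum, index=pd.RangeIndex(1, n_herds + 1), name="stratum")

    ped_idx = pedigree.set_index("animal")
    cows = pedigree.loc[(pedigree["sire"] != 0) & (pedigree["dam"] != 0), "animal"].to_numpy()

    sd_p = np.sqrt(truth.sigma2_p)
    sd_e = {"low": np.sqrt(truth.sigma2_e_low), "high": np.sqrt(truth.sigma2_e_high)}
    col = {"low": 0, "high": 1}
    cg_effects: dict = {}
    rows = []
    n_clamped = 0
    for cow in cows:
        herd = 1 + int(rng.integers(0, n_herds))
        strat = herd_stratum.loc[herd]
        n_par = 1 + int(rng.integers(0, max_parities))
        first = years[int(rng.integers(0, max(1, len(years) - n_par + 1)))]
        p_c = rng.normal(0.0, sd_p)
        age0 = float(rng.normal(30.0, 2.0))
        a_c = bv[rs.index[cow], col[strat]]
        sire = ped_idx.at[cow, "sire"]
        for k in range(n_par):
            year = first + k
            month = 1 + int(rng.integers(0, 12))
            day = 1 + int(rng.integers(0, 28))
            season = "dry" if 4 <= month <= 9 else "rainy"
            key = (herd, year, season)
            if key not in cg_effects:
                cg_effects[key] = rng.normal(0.0, truth.cg_effect_sd)
            age = age0 + 13.0 * k + float(rng.normal(0.0, 1.0))
            dh = compute_dh(
                {
                    "b1": ped_idx.at[sire, "frac_breed1"],
                    "b2": ped_idx.at[sire, "frac_breed2"],
                },
                {
                    "b1": ped_idx.at[ped_idx.at[cow, "dam"], "frac_breed1"],
                    "b2": ped_idx.at[ped_idx.at[cow, "dam"], "frac_breed2"],
                },
            )
            ac = age - 60.0
            y305 = (
                truth.base_mean
                + herd_dev[herd - 1]
                + cg_effects[key]
                + truth.beta_age1 * ac
                + truth.beta_age2 * ac * ac
                + truth.beta_dh * dh
                + a_c
                + p_c
                + rng.normal(0.0, sd_e[strat])
            )
            ll = float(np.round(rng.uniform(180.0, 400.0)))
            my = y305 - truth.b1_ll * (ll - 305.0)
            if my < 0:
                my = 0.0
                n_clamped += 1
            rows.append(
                (
                    cow,
                    sire,
                    herd,
                    pd.Timestamp(year=year, month=month, day=day),
                    round(age, 1),
                    ll,
                    round(my, 2),
                )
            )
    records = pd.DataFrame(
        rows, columns=["cow", "sire", "herd", "calving_date", "age_months", "ll_days", "my_kg"]
    )
    return SimulatedDataset(
        pedigree=pedigree,
        records=records,
        true_ebv=true_ebv,
        truth=truth,
        herd_stratum=herd_stratum,
        n_clamped=n_clamped,
    )


def simulate(
    truth: TrueParameters,
    n_sires: int = 40,
    daughters_per_sire: int = 30,
    n_dams: int | None = None,
    breed_profile: str = "girolando_sire",
    n_herds: int = 20,
    years=range(2014, 2018),
    max_parities: int = 3,
) -> SimulatedDataset:
    """Pedigree + records in one call; the default arguments are the
    package's standard recovery scenario (40 sires x 30 daughters)."""
    if n_dams is None:
        n_dams = n_sires * daughters_per_sire
    ped = simulate_pedigree(n_sires, n_dams, daughters_per_sire, breed_profile, seed=truth.seed)
    return simulate_records(ped, truth, n_herds=n_herds, years=years, max_parities=max_parities)


def write_pedigree_csv(pedigree: pd.DataFrame, path) -> None:
    out = pedigree.copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_records_csv(records: pd.DataFrame, path) -> None:
    out = records[["cow", "sire", "herd", "calving_date", "age_months", "ll_days", "my_kg"]].copy()
    out["calving_date"] = pd.to_datetime(out["calving_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def load_records_csv(path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    rec["calving_date"] = pd.to_datetime(rec["calving_date"])
    return rec
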