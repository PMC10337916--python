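"""Bayesian repeatability animal models fitted by Gibbs sampling.

Single-trait ("general") analysis:

    y = Xb + Za + Wp + e,   a ~ N(0, A sigma2_a),  p ~ N(0, I sigma2_p),
                            e ~ N(0, I sigma2_e)

with fixed effects b = contemporary groups plus age (linear, quadratic) and
direct heterozygosity covariates.  Two-trait ("HV") analysis treats the
milk yield expressed in low- and high-SD herd-year classes as distinct
traits: a carries two breeding values per animal with covariance
G0 (x) A; residual and permanent-environment covariances across traits are
fixed at zero because no cow has records in both classes (class is a
herd-year property), so they are not estimable.

Variance components get conjugate priors — scaled inverse chi-square for
the scalars, inverse-Wishart for G0 — with weakly informative defaults:
nu = dim + 2 and scales from a 10/20/70 additive/permanent/residual split
of the within-contemporary-group phenotypic variance.

The chain is configured by total iterations, burn-in and thinning interval;
retained draws = floor((n_iter - burn_in)/thin), e.g. the full-length
configuration 300,000/30,000/10 retains exactly 27,000 draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _kernels
from .pedigree import RelationshipStructure


class NumericalFailureError(RuntimeError):
    """A variance draw went non-finite; carries the iteration index."""


# chain presets: the full-length configuration retains 27,000 draws; the
# desk configuration is the package default for interactive and test use.
FULL_CHAIN = dict(n_iter=300_000, burn_in=30_000, thin=10)
DESK_CHAIN = dict(n_iter=30_000, burn_in=3_000, thin=10)


@dataclass
class ChainConfig:
    """Gibbs chain length, thinning, seed and prior hyperparameters.

    Prior scales left at ``None`` are derived from the data at fit time
    (within-CG phenotypic variance split 10/20/70 across a/p/e).
    """

    n_iter: int = 30_000
    burn_in: int = 3_000
    thin: int = 10
    seed: int = 0
    nu_a: float = 3.0
    s2_a: float | None = None
    nu_p: float = 3.0
    s2_p: float | None = None
    nu_e: float = 3.0
    s2_e: float | None = None
    nu_g: float = 4.0
    g_scale: np.ndarray | None = None  # 2x2 inverse-Wishart prior scale
    # generalized-Gibbs scale/shear moves (exact; dramatically better mixing
    # of variance components on weakly informative data)
    group_moves: bool = True

    def __post_init__(self):
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ModelMatrices:
    """Design information for one analysis, in index (not matrix) form.

    The incidence matrices X, Z, W of the model are stored as level codes
    per record; the samplers rebuild the per-level record lists they need.
    """

    y: np.ndarray
    cov: np.ndarray          # centered covariates: age, age^2, DH
    cg: np.ndarray           # contemporary-group code per record
    n_cg: int
    cg_labels: list
    animal: np.ndarray       # record -> renumbered animal index
    n_animals: int
    animal_ids: list
    pe: np.ndarray           # record -> permanent-environment (cow) code
    n_pe: int
    pe_labels: list
    trait: np.ndarray        # 0 = low / single, 1 = high
    mode: str
    cg_trait: np.ndarray | None = None
    an_trait: np.ndarray | None = None   # trait of an animal's own records; -1 none
    pe_trait: np.ndarray | None = None

    @property
    def n_records(self) -> int:
        return len(self.y)


COVARIATES = ("age_months", "age_sq", "dh")


def assemble(records: pd.DataFrame, structure: RelationshipStructure, mode: str = "single") -> ModelMatrices:
    """Build design codes from prepared records.

    Age and age-squared are centered at their (per-trait) means for mixing;
    DH enters as-is.  In two-trait mode contemporary groups are nested
    within trait — automatic here since the SD class is a herd-year
    property, asserted all the same — and each cow must appear in exactly
    one trait.
    """
    if mode not in ("single", "two_trait"):
        raise ValueError(f"unknown mode {mode!r}")
    needed = ["my305_kg", "cg_key", "age_months", "dh", "cow"]
    if mode == "two_trait":
        needed.append("sd_class")
    for c in needed:
        if c not in records.columns or records[c].isna().any():
            raise ValueError(f"records not prepared: column {c!r} missing or has NaN")
    n = len(records)
    if n == 0:
        raise ValueError("no records")

    if mode == "two_trait":
        trait = (records["sd_class"].to_numpy() == "high").astype(np.int64)
        cross = records.groupby("cg_key")["sd_class"].nunique()
        if (cross > 1).any():
            raise ValueError("contemporary group spans both SD classes")
    else:
        trait = np.zeros(n, dtype=np.int64)

    y = records["my305_kg"].to_numpy(dtype=float)
    age = records["age_months"].to_numpy(dtype=float)
    dh = records["dh"].to_numpy(dtype=float)
    age2 = age * age
    cov = np.column_stack([age, age2, dh])
    for t in np.unique(trait):
        m = trait == t
        cov[m, 0] -= cov[m, 0].mean()
        cov[m, 1] -= cov[m, 1].mean()

    cg_codes, cg_labels = pd.factorize(records["cg_key"], sort=True)
    pe_codes, pe_labels = pd.factorize(records["cow"], sort=True)
    missing = [c for c in pe_labels if c not in structure.index]
    if missing:
        raise ValueError(f"cows missing from pedigree order: {missing[:5]}")
    animal = np.array([structure.index[c] for c in records["cow"]], dtype=np.int64)

    cg_trait = np.zeros(len(cg_labels), dtype=np.int64)
    for code, t in zip(cg_codes, trait):
        cg_trait[code] = t
    pe_trait = np.full(len(pe_labels), -1, dtype=np.int64)
    for code, t in zip(pe_codes, trait):
        if pe_trait[code] not in (-1, t):
            raise ValueError("a cow has records in both SD classes")
        pe_trait[code] = t
    an_trait = np.full(structure.n_animals, -1, dtype=np.int64)
    for ai, t in zip(animal, trait):
        an_trait[ai] = t

    return ModelMatrices(
        y=y,
        cov=cov,
        cg=cg_codes.astype(np.int64),
        n_cg=len(cg_labels),
        cg_labels=list(cg_labels),
        animal=animal,
        n_animals=structure.n_animals,
        animal_ids=list(structure.order),
        pe=pe_codes.astype(np.int64),
        n_pe=len(pe_labels),
        pe_labels=list(pe_labels),
        trait=trait,
        mode=mode,
        cg_trait=cg_trait,
        an_trait=an_trait,
        pe_trait=pe_trait,
    )


def _csr_by_level(codes: np.ndarray, n_levels: int):
    order = np.argsort(codes, kind="stable").astype(np.int64)
    counts = np.bincount(codes, minlength=n_levels)
    ptr = np.zeros(n_levels + 1, dtype=np.int64)
    ptr[1:] = np.cumsum(counts)
    return ptr, order


def _within_cg_variance(y: np.ndarray, cg: np.ndarray, cov: np.ndarray = None, mask=None) -> float:
    """Phenotypic variance net of the fixed part (CG means and covariates).

    Used only to set prior scales; covariate effects (age especially) vary
    within contemporary groups and would otherwise inflate the scales far
    above the random-component magnitudes.
    """
    if mask is not None:
        y, cg = y[mask], cg[mask]
        cov = cov[mask] if cov is not None else None
    df = pd.DataFrame({"y": y, "cg": cg})
    resid = (df["y"] - df.groupby("cg")["y"].transform("mean")).to_numpy()
    if cov is not None and cov.shape[1] > 0:
        xc = pd.DataFrame(cov)
        xc["cg"] = cg
        xc = xc.groupby("cg").transform(lambda s: s - s.mean()).to_numpy()
        beta, *_ = np.linalg.lstsq(xc, resid, rcond=None)
        resid = resid - xc @ beta
    v = float(np.var(resid, ddof=1))
    return v if v > 0 else float(np.var(y)) + 1.0


@dataclass
class GibbsSamples:
    """Retained draws from one chain."""

    vc: pd.DataFrame            # variance components per retained draw
    a: np.ndarray               # (nret, n_traits, n_animals) breeding values
    b: np.ndarray               # fixed effects (CG levels then covariates)
    p: np.ndarray               # permanent-environment effects
    mode: str
    config: ChainConfig
    animal_ids: list
    pe_labels: list

    @property
    def n_retained(self) -> int:
        return len(self.vc)


def _resolve_priors(cfg: ChainConfig, mm: ModelMatrices):
    # Default scales put each prior's scale parameter at its share of the
    # fixed-effect-adjusted phenotypic variance (10/20/70 a/p/e split);
    # explicit user scales are passed through unchanged.
    if mm.mode == "single":
        varw = _within_cg_variance(mm.y, mm.cg, mm.cov)
        sa = cfg.s2_a if cfg.s2_a is not None else 0.1 * varw
        sp = cfg.s2_p if cfg.s2_p is not None else 0.2 * varw
        se = cfg.s2_e if cfg.s2_e is not None else 0.7 * varw
        return sa, sp, se
    varw = [
        _within_cg_variance(mm.y, mm.cg, mm.cov, mm.trait == t) if (mm.trait == t).any() else 1.0
        for t in (0, 1)
    ]
    if cfg.g_scale is not None:
        g0 = np.asarray(cfg.g_scale, dtype=float)
    else:
        g0 = np.diag([0.1 * varw[0], 0.1 * varw[1]])
    sp = [cfg.s2_p if cfg.s2_p is not None else 0.2 * varw[t] for t in (0, 1)]
    se = [cfg.s2_e if cfg.s2_e is not None else 0.7 * varw[t] for t in (0, 1)]
    return g0, sp, se


def gibbs_single(
    mm: ModelMatrices,
    a_inv,
    cfg: ChainConfig,
    sample_variances: bool = True,
    init: tuple | None = None,
) -> GibbsSamples:
    """Run the single-trait chain; returns retained draws of (b, a, p, VC)."""
    if mm.mode != "single":
        raise ValueError("matrices were assembled for two_trait mode")
    sa0, sp0, se0 = _resolve_priors(cfg, mm)
    init_a, init_p, init_e = init if init is not None else (sa0 or 1.0, sp0 or 1.0, se0 or 1.0)
    ai = a_inv.tocsr() if a_inv is not None else None
    nret = cfg.n_retained
    out_vc = np.empty((nret, 3))
    out_a = np.empty((nret, mm.n_animals))
    out_b = np.empty((nret, mm.n_cg + mm.cov.shape[1]))
    out_p = np.empty((nret, mm.n_pe))
    cgptr, cgrec = _csr_by_level(mm.cg, mm.n_cg)
    anptr, anrec = _csr_by_level(mm.animal, mm.n_animals)
    peptr, perec = _csr_by_level(mm.pe, mm.n_pe)
    if ai is None:
        aiptr = np.zeros(mm.n_animals + 1, dtype=np.int64)
        aiidx = np.zeros(0, dtype=np.int64)
        aidat = np.zeros(0, dtype=float)
    else:
        aiptr = ai.indptr.astype(np.int64)
        aiidx = ai.indices.astype(np.int64)
        aidat = ai.data.astype(float)
    status = _kernels.run_single(
        mm.y,
        np.ascontiguousarray(mm.cov),
        cgptr,
        cgrec,
        anptr,
        anrec,
        mm.animal,
        peptr,
        perec,
        mm.pe,
        aiptr,
        aiidx,
        aidat,
        cfg.n_iter,
        cfg.burn_in,
        cfg.thin,
        cfg.seed % (2**31),
        cfg.nu_a,
        sa0,
        cfg.nu_p,
        sp0,
        cfg.nu_e,
        se0,
        float(init_a),
        float(init_p),
        float(init_e),
        sample_variances,
        cfg.group_moves,
        out_vc,
        out_a,
        out_b,
        out_p,
    )
    if status >= 0:
        raise NumericalFailureError(f"non-finite variance draw at iteration {status}")
    vc = pd.DataFrame(out_vc, columns=["sigma2_a", "sigma2_p", "sigma2_e"])
    return GibbsSamples(
        vc=vc,
        a=out_a[:, None, :],
        b=out_b,
        p=out_p,
        mode="single",
        config=cfg,
        animal_ids=mm.animal_ids,
        pe_labels=mm.pe_labels,
    )


def gibbs_two_trait(mm: ModelMatrices, a_inv, cfg: ChainConfig, sample_variances: bool = True) -> GibbsSamples:
    """Run the two-trait HV chain; G0 is sampled inverse-Wishart per draw."""
    if mm.mode != "two_trait":
        raise ValueError("matrices were assembled for single mode")
    g0_prior, sp0, se0 = _resolve_priors(cfg, mm)
    ai = a_inv.tocsr()
    nret = cfg.n_retained
    out_vc = np.empty((nret, 7))
    out_a = np.empty((nret, 2, mm.n_animals))
    out_b = np.empty((nret, mm.n_cg + 2 * mm.cov.shape[1]))
    out_p = np.empty((nret, mm.n_pe))
    cgptr, cgrec = _csr_by_level(mm.cg, mm.n_cg)
    anptr, anrec = _csr_by_level(mm.animal, mm.n_animals)
    peptr, perec = _csr_by_level(mm.pe, mm.n_pe)
    status = _kernels.run_two_trait(
        mm.y,
        np.ascontiguousarray(mm.cov),
        mm.trait,
        cgptr,
        cgrec,
        mm.cg_trait,
        anptr,
        anrec,
        mm.an_trait,
        mm.animal,
        peptr,
        perec,
        mm.pe_trait,
        mm.pe,
        ai.indptr.astype(np.int64),
        ai.indices.astype(np.int64),
        ai.data.astype(float),
        cfg.n_iter,
        cfg.burn_in,
        cfg.thin,
        cfg.seed % (2**31),
        cfg.nu_g,
        float(g0_prior[0, 0]),
        float(g0_prior[0, 1]),
        float(g0_prior[1, 1]),
        cfg.nu_p,
        float(sp0[0]),
        float(sp0[1]),
        cfg.nu_e,
        float(se0[0]),
        float(se0[1]),
        float(g0_prior[0, 0] or 1.0),
        float(g0_prior[0, 1]),
        float(g0_prior[1, 1] or 1.0),
        sample_variances,
        cfg.group_moves,
        out_vc,
        out_a,
        out_b,
        out_p,
    )
    if status >= 0:
        raise NumericalFailureError(f"invalid G0/variance draw at iteration {status}")
    vc = pd.DataFrame(
        out_vc,
        columns=["g_11", "g_12", "g_22", "sigma2_p_low", "sigma2_p_high", "sigma2_e_low", "sigma2_e_high"],
    )
    return GibbsSamples(
        vc=vc,
        a=out_a,
        b=out_b,
        p=out_p,
        mode="two_trait",
        config=cfg,
        animal_ids=mm.animal_ids,
        pe_labels=mm.pe_labels,
    )


# ---------------------------------------------------------------------------
# posterior summaries and genetic parameters


@dataclass
class PosteriorSummary:
    mean: float
    sd: float
    hpd95_low: float
    hpd95_high: float


def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    k = int(np.floor(mass * n))
    if k < 1 or k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def summarize(draws, mass: float = 0.95) -> PosteriorSummary:
    """Posterior mean, SD and HPD interval of one monitored quantity."""
    x = np.asarray(draws, dtype=float)
    if len(x) < 100:
        raise ValueError(f"need >= 100 retained draws, got {len(x)}")
    lo, hi = hpd_interval(x, mass)
    return PosteriorSummary(mean=float(x.mean()), sd=float(x.std(ddof=1)), hpd95_low=lo, hpd95_high=hi)


def heritability(sigma2_a, sigma2_p, sigma2_e):
    """h2 = sigma2_a / (sigma2_a + sigma2_p + sigma2_e)."""
    tot = sigma2_a + sigma2_p + sigma2_e
    return sigma2_a / tot


def repeatability(sigma2_a, sigma2_p, sigma2_e):
    """rep = (sigma2_a + sigma2_p) / (sigma2_a + sigma2_p + sigma2_e)."""
    tot = sigma2_a + sigma2_p + sigma2_e
    return (sigma2_a + sigma2_p) / tot


def derive_parameters(samples: GibbsSamples) -> dict:
    """Per-draw heritability, repeatability (and r_g), plus summaries.

    Also reports the point ratio computed from posterior-mean components,
    the quantity published summary tables print.
    """
    vc = samples.vc
    draws = pd.DataFrame(index=vc.index)
    if samples.mode == "single":
        draws["h2"] = heritability(vc["sigma2_a"], vc["sigma2_p"], vc["sigma2_e"])
        draws["rep"] = repeatability(vc["sigma2_a"], vc["sigma2_p"], vc["sigma2_e"])
        m = vc.mean()
        point = {
            "h2": float(heritability(m["sigma2_a"], m["sigma2_p"], m["sigma2_e"])),
            "rep": float(repeatability(m["sigma2_a"], m["sigma2_p"], m["sigma2_e"])),
        }
    else:
        for t, lab in ((0, "low"), (1, "high")):
            g = vc[f"g_{t+1}{t+1}"]
            draws[f"h2_{lab}"] = heritability(g, vc[f"sigma2_p_{lab}"], vc[f"sigma2_e_{lab}"])
            draws[f"rep_{lab}"] = repeatability(g, vc[f"sigma2_p_{lab}"], vc[f"sigma2_e_{lab}"])
        draws["r_g"] = vc["g_12"] / np.sqrt(vc["g_11"] * vc["g_22"])
        m = vc.mean()
        point = {
            "h2_low": float(heritability(m["g_11"], m["sigma2_p_low"], m["sigma2_e_low"])),
            "h2_high": float(heritability(m["g_22"], m["sigma2_p_high"], m["sigma2_e_high"])),
            "r_g": float(m["g_12"] / np.sqrt(m["g_11"] * m["g_22"])),
        }
    summaries = {c: summarize(draws[c]) for c in draws.columns}
    return {"draws": draws, "summaries": summaries, "point": point}


# ---------------------------------------------------------------------------
# estimator façade


class GibbsAnimalModel(BaseEstimator):
    """Scikit-learn-style front end for the Gibbs-sampled animal model.

    Parameters mirror :class:`ChainConfig`; ``fit`` takes assembled
    :class:`ModelMatrices` and the sparse pedigree A-inverse (pedigree input
    does not fit sklearn's tabular X/y contract, so this estimator composes
    with sklearn tooling through get_params/set_params and cloning only).

    Attributes set by fit (trailing underscore): ``samples_``,
    ``vc_summary_``, ``params_``, ``ebv_``, ``pev_``, ``n_retained_``.
    """

    def __init__(
        self,
        mode: str = "single",
        n_iter: int = 30_000,
        burn_in: int = 3_000,
        thin: int = 10,
        seed: int = 0,
        priors: Mapping | None = None,
    ):
        self.mode = mode
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.priors = priors

    def _config(self) -> ChainConfig:
        extra = dict(self.priors) if self.priors else {}
        return ChainConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin, seed=self.seed, **extra
        )

    def fit(self, matrices: ModelMatrices, a_inverse):
        if matrices.mode != self.mode:
            raise ValueError(f"matrices assembled for {matrices.mode!r}, estimator mode {self.mode!r}")
        cfg = self._config()
        if self.mode == "single":
            self.samples_ = gibbs_single(matrices, a_inverse, cfg)
        else:
            self.samples_ = gibbs_two_trait(matrices, a_inverse, cfg)
        self.n_retained_ = self.samples_.n_retained
        self.vc_summary_ = {c: summarize(self.samples_.vc[c]) for c in self.samples_.vc.columns}
        self.params_ = derive_parameters(self.samples_)
        ebv = self.samples_.a.mean(axis=0)       # (n_traits, n_animals)
        pev = self.samples_.a.var(axis=0, ddof=1)
        idx = pd.Index(matrices.animal_ids, name="animal")
        cols = ["general"] if self.mode == "single" else ["low", "high"]
        self.ebv_ = pd.DataFrame(ebv.T, index=idx, columns=cols)
        self.pev_ = pd.DataFrame(pev.T, index=idx, columns=cols)
        return self

    def predict(self, animal_ids=None) -> pd.DataFrame:
        """Posterior-mean breeding values, optionally for a subset of animals."""
        if not hasattr(self, "ebv_"):
            raise ValueError("model is not fitted")
        return self.ebv_ if animal_ids is None else self.ebv_.loc[list(animal_ids)]
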