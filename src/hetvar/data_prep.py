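"""Data-consistency pipeline for multi-herd lactation records.

Implements the editing rules a pedigree-based genetic evaluation of 305-day
milk yield needs before model fitting:

1. direct heterozygosity (DH) of each cow from the breed composition of her
   sire and dam,
2. standardization of total lactation yield to 305 days,
   ``MY305 = MY + b1 (LL - 305)`` with b1 the OLS slope of MY on LL,
3. calving seasons (dry: April–September, rainy: October–March) and
   contemporary groups (herd x calving year x season),
4. record filters: missing ancestry or birth date, MY305 cap, age cap, and
   a minimum contemporary-group size,
5. standard-deviation (SD) classes per herd-year: the herd-year mean of
   MY305 is standardized against the overall record-level mean and SD, and
   the herd-year is labelled ``low`` iff z <= 0, else ``high``,
6. connectedness: sires must have at least two daughters with retained
   records in each SD class, so the between-class genetic covariance is
   estimable.

Records live in a pandas DataFrame with columns
``cow, sire, herd, calving_date, age_months, ll_days, my_kg`` plus the
derived columns ``dh, my305_kg, season, year, cg_key, sd_class``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateRegressionError(ValueError):
    """MY-on-LL regression is undefined (all lactation lengths equal)."""


class DegenerateDistributionError(ValueError):
    """The record-level SD of MY305 is zero; z-scores are undefined."""


# ---------------------------------------------------------------------------
# heterozygosity


def _validate_composition(comp: Mapping[str, float], label: str) -> dict:
    total = float(sum(comp.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{label} breed fractions sum to {total!r}, not 1")
    if any(f < -1e-12 or f > 1 + 1e-12 for f in comp.values()):
        raise ValueError(f"{label} breed fractions outside [0, 1]")
    return dict(comp)


def compute_dh(sire: Mapping[str, float], dam: Mapping[str, float]) -> float:
    """Direct heterozygosity of a two-breed cross.

    DH = a1_sire * a2_dam + a2_sire * a1_dam, the expected fraction of loci
    carrying one allele from each breed.  1.0 for a pure cross (e.g. pure
    Holstein sire x pure Gir dam), 0.0 within a pure breed.
    """
    s = _validate_composition(sire, "sire")
    d = _validate_composition(dam, "dam")
    breeds = sorted(set(s) | set(d))
    if len(breeds) != 2:
        raise ValueError(f"expected two breeds, got {breeds}")
    b1, b2 = breeds
    return float(s.get(b1, 0.0) * d.get(b2, 0.0) + s.get(b2, 0.0) * d.get(b1, 0.0))


def add_heterozygosity(records: pd.DataFrame, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Attach each cow's DH, computed from her parents' breed fractions.

    Cows whose parents are unknown (or absent from the pedigree) get NaN;
    the ancestry filter removes them later.
    """
    ped = pedigree.set_index("animal")
    dh_by_cow = {}
    for cow in records["cow"].unique():
        if cow not in ped.index:
            dh_by_cow[cow] = np.nan
            continue
        row = ped.loc[cow]
        s_id, d_id = row["sire"], row["dam"]
        if s_id == 0 or d_id == 0 or s_id not in ped.index or d_id not in ped.index:
            dh_by_cow[cow] = np.nan
            continue
        sire_c = {"b1": ped.at[s_id, "frac_breed1"], "b2": ped.at[s_id, "frac_breed2"]}
        dam_c = {"b1": ped.at[d_id, "frac_breed1"], "b2": ped.at[d_id, "frac_breed2"]}
        dh_by_cow[cow] = compute_dh(sire_c, dam_c)
    out = records.copy()
    out["dh"] = out["cow"].map(dh_by_cow)
    return out


# ---------------------------------------------------------------------------
# 305-day standardization


@dataclass
class RegressionAdjustment:
    """OLS slope of total yield on lactation length, kg per day."""

    b1: float
    n_used: int


def estimate_b1(records: pd.DataFrame, groupby: str | None = None) -> RegressionAdjustment:
    """OLS slope of MY on LL over the supplied (within-breed) records.

    With ``groupby`` set (e.g. ``"cg_key"``), MY and LL are demeaned within
    the named grouping column first, giving the pooled within-group slope.
    Herd-to-herd production differences then stay out of the regression
    noise — the estimator a pipeline should use once management groups are
    known; the plain overall slope remains the default.
    """
    ll = np.asarray(records["ll_days"], dtype=float)
    my = np.asarray(records["my_kg"], dtype=float)
    if len(ll) < 2:
        raise ValueError("need at least two records to regress MY on LL")
    if groupby is not None:
        g = records[groupby]
        ll = ll - records.groupby(g)["ll_days"].transform("mean").to_numpy(dtype=float)
        my = my - records.groupby(g)["my_kg"].transform("mean").to_numpy(dtype=float)
    if np.ptp(ll) == 0:
        raise DegenerateRegressionError("all lactation lengths equal; slope undefined")
    fit = stats.linregress(ll, my)
    return RegressionAdjustment(b1=float(fit.slope), n_used=len(ll))


def standardize_my305(my_kg, ll_days, b1: float):
    """MY305 = MY + b1 (LL - 305); two-sided, raising short lactations' MY
    when b1 < 0 and vice versa."""
    return np.asarray(my_kg, dtype=float) + b1 * (np.asarray(ll_days, dtype=float) - 305.0)


# ---------------------------------------------------------------------------
# seasons and contemporary groups

DRY_MONTHS = frozenset(range(4, 10))


def assign_season(calving_month: int) -> str:
    """Dry season April–September, rainy October–March."""
    m = int(calving_month)
    if not 1 <= m <= 12:
        raise ValueError(f"month {calving_month!r} outside 1..12")
    return "dry" if m in DRY_MONTHS else "rainy"


def build_contemporary_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Attach season, calving year, and the herd-year-season cg_key."""
    out = records.copy()
    dates = pd.to_datetime(out["calving_date"])
    out["year"] = dates.dt.year
    out["season"] = dates.dt.month.map(lambda m: assign_season(m))
    out["cg_key"] = (
        out["herd"].astype(str) + "|" + out["year"].astype(str) + "|" + out["season"]
    )
    return out


# ---------------------------------------------------------------------------
# filters


@dataclass
class FilterReport:
    """Per-rule removal counts; conserves input = retained + sum(removed)."""

    n_input: int = 0
    no_ancestry: int = 0
    my305_cap: int = 0
    age_cap: int = 0
    small_cg: int = 0
    class_consistency: int = 0
    connectedness: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return (
            self.no_ancestry
            + self.my305_cap
            + self.age_cap
            + self.small_cg
            + self.class_consistency
            + self.connectedness
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["removed_total"] = self.removed
        return d


def apply_filters(
    records: pd.DataFrame,
    pedigree: pd.DataFrame,
    my305_cap: float = 25_000.0,
    age_cap: float = 120.0,
    cg_min: int = 4,
    min_ll: float | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Record-level edits in fixed order, then one contemporary-group sweep.

    Order: (1) cows lacking a known sire, dam, or birth date; (2) MY305
    above the cap; (3) age at calving above the cap; (4) contemporary
    groups left with fewer than ``cg_min`` records.  ``min_ll`` is off by
    default (short lactations are kept); set it to also drop LL below a
    floor during step 2.
    """
    rep = FilterReport(n_input=len(records))
    ped = pedigree.set_index("animal")

    ok_cows = set()
    for cow in records["cow"].unique():
        if cow not in ped.index:
            continue
        row = ped.loc[cow]
        if row["sire"] == 0 or row["dam"] == 0:
            continue
        if "birth_date" in ped.columns and pd.isna(row["birth_date"]):
            continue
        ok_cows.add(cow)
    keep = records["cow"].isin(ok_cows)
    rep.no_ancestry = int((~keep).sum())
    out = records[keep]

    keep = out["my305_kg"] <= my305_cap
    if min_ll is not None:
        keep &= out["ll_days"] >= min_ll
    rep.my305_cap = int((~keep).sum())
    out = out[keep]

    keep = out["age_months"] <= age_cap
    rep.age_cap = int((~keep).sum())
    out = out[keep]

    sizes = out.groupby("cg_key")["cow"].transform("size")
    keep = sizes >= cg_min
    rep.small_cg = int((~keep).sum())
    out = out[keep].copy()

    rep.retained = len(out)
    assert rep.retained + rep.removed == rep.n_input
    return out, rep


# ---------------------------------------------------------------------------
# SD classes


@dataclass
class HerdYearClass:
    """A herd-year cell: its MY305 mean X, z = (X - mu)/sigma, and class."""

    herd_id: object
    year: int
    class_mean: float
    z: float
    sd_class: str


def assign_sd_classes(
    records: pd.DataFrame, z_basis: str = "records"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each herd-year (and its records) ``low`` (z <= 0) or ``high``.

    mu and sigma are the mean and SD of MY305 over all retained records
    (``z_basis='records'``, the default reading of "general average of
    production"), or over the herd-year class means (``'class-means'``).
    """
    if len(records) == 0:
        raise ValueError("no records to class")
    my = records["my305_kg"].to_numpy(dtype=float)
    means = records.groupby(["herd", "year"])["my305_kg"].mean()
    if z_basis == "records":
        mu, sigma = float(my.mean()), float(my.std(ddof=1))
    elif z_basis == "class-means":
        mu, sigma = float(means.mean()), float(means.std(ddof=1))
    else:
        raise ValueError(f"unknown z_basis {z_basis!r}")
    if not sigma > 0:
        raise DegenerateDistributionError("zero SD of MY305; z undefined")
    hy = means.rename("class_mean").reset_index()
    hy["z"] = (hy["class_mean"] - mu) / sigma
    hy["sd_class"] = np.where(hy["z"] <= 0, "low", "high")
    out = records.merge(hy[["herd", "year", "sd_class"]], on=["herd", "year"], how="left")
    out.index = records.index
    return out, hy


def enforce_cow_class_consistency(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep each cow's records in a single SD class.

    The SD class is a herd-year property, so a cow recorded over several
    years in a herd near the class boundary can straddle both classes; the
    two-trait model treats the permanent-environment effect as
    trait-specific and needs every cow in exactly one class.  For such
    cows the majority class is kept (ties: the class of her earliest
    calving); the minority records are dropped and counted.
    """
    spans = records.groupby("cow")["sd_class"].nunique()
    bad = spans.index[spans > 1]
    if len(bad) == 0:
        return records, 0
    keep_mask = pd.Series(True, index=records.index)
    for cow in bad:
        sub = records[records["cow"] == cow]
        counts = sub["sd_class"].value_counts()
        if counts.iloc[0] > counts.iloc[1:].max():
            chosen = counts.index[0]
        else:
            chosen = sub.sort_values("calving_date").iloc[0]["sd_class"]
        keep_mask[sub.index[sub["sd_class"] != chosen]] = False
    dropped = int((~keep_mask).sum())
    return records[keep_mask].copy(), dropped


# ---------------------------------------------------------------------------
# connectedness


def enforce_connectedness(
    records: pd.DataFrame, min_daughters: int = 2
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep only sires with >= min_daughters distinct daughters in *each* class.

    Iterates to a fixed point; with frozen classes one sire's removal cannot
    change another sire's daughter counts, so the loop's second pass is a
    no-op check.  Contemporary-group sizes are deliberately not re-checked
    here (documented pipeline order).
    """
    rep = FilterReport(n_input=len(records))
    out = records
    while True:
        counts = out.groupby(["sire", "sd_class"])["cow"].nunique().unstack(fill_value=0)
        for cls in ("low", "high"):
            if cls not in counts.columns:
                counts[cls] = 0
        good = counts.index[(counts["low"] >= min_daughters) & (counts["high"] >= min_daughters)]
        keep = out["sire"].isin(good)
        if keep.all():
            break
        out = out[keep]
        if len(out) == 0:
            break
    rep.connectedness = rep.n_input - len(out)
    rep.retained = len(out)
    return out.copy(), rep


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PrepResult:
    records: pd.DataFrame
    b1: RegressionAdjustment
    report: FilterReport
    herd_year_classes: pd.DataFrame


def prepare(
    records: pd.DataFrame,
    pedigree: pd.DataFrame,
    my305_cap: float = 25_000.0,
    age_cap: float = 120.0,
    cg_min: int = 4,
    min_daughters: int = 2,
    min_ll: float | None = None,
    z_basis: str = "records",
    b1_basis: str = "cg_key",
) -> PrepResult:
    """Run the full consistency pipeline on raw records.

    DH and contemporary groups are computed first, then the MY-on-LL slope
    (within contemporary groups by default, ``b1_basis="overall"`` for the
    plain pooled slope) and MY305, the fixed filter order, SD classes, the
    cow class-consistency rule, and finally sire connectedness.
    """
    out = add_heterozygosity(records, pedigree)
    out = build_contemporary_groups(out)
    b1 = estimate_b1(out, groupby=b1_basis if b1_basis != "overall" else None)
    out["my305_kg"] = standardize_my305(out["my_kg"], out["ll_days"], b1.b1)
    out, rep = apply_filters(
        out, pedigree, my305_cap=my305_cap, age_cap=age_cap, cg_min=cg_min, min_ll=min_ll
    )
    out, hy = assign_sd_classes(out, z_basis=z_basis)
    out, rep.class_consistency = enforce_cow_class_consistency(out)
    out, conn_rep = enforce_connectedness(out, min_daughters=min_daughters)
    rep.connectedness = conn_rep.connectedness
    rep.retained = len(out)
    assert rep.retained + rep.removed == rep.n_input
    return PrepResult(records=out.reset_index(drop=True), b1=b1, report=rep, herd_year_classes=hy)
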