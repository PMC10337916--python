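"""Published reference values for cross-checking the parameter arithmetic.

A Bayesian heterogeneity-of-variance evaluation of 305-day milk yield in
Brazilian herds (daughters of Girolando, Gir and Holstein sires) published
descriptive statistics and posterior-mean variance components per analysis
(general, low-SD class, high-SD class).  The raw data are proprietary, but
the printed summaries are internally checkable: heritability and
repeatability must equal their defining ratios of the printed components,
and the coefficient of variation must equal SD/mean.  This module bundles
those printed values as inputs for the package's arithmetic cross-checks.

Descriptive cells are (mean_kg, sd_kg, cv_pct, n_lactations, n_cg).
"""

from __future__ import annotations

from .gibbs_engine import heritability, repeatability

ANALYSES = ("general", "low", "high")

DESCRIPTIVE = {
    "girolando": {
        "general": (4065.10, 2080.15, 51.17, 10482, 1862),
        "low": (2883.56, 1463.95, 50.77, 4951, 915),
        "high": (5122.75, 1978.36, 38.62, 5531, 947),
    },
    "gir": {
        "general": (5063.16, 2674.01, 52.81, 16439, 2846),
        "low": (3542.61, 1992.54, 56.25, 7505, 1477),
        "high": (6340.51, 2499.64, 39.42, 8934, 1369),
    },
    "holstein": {
        "general": (5247.84, 2576.54, 49.10, 65235, 5551),
        "low": (3822.28, 1954.08, 51.12, 29049, 2746),
        "high": (6392.23, 2441.63, 38.20, 36186, 2805),
    },
}

# posterior means of (sigma2_a, sigma2_p, sigma2_e) with the printed h2/rep
VARIANCE_COMPONENTS = {
    "girolando": {
        "general": dict(sigma2_a=2114.34, sigma2_p=5465.80, sigma2_e=16927.77, h2=0.09, rep=0.31),
        "low": dict(sigma2_a=2077.75, sigma2_p=3507.01, sigma2_e=11711.42, h2=0.12, rep=0.32),
        "high": dict(sigma2_a=2979.68, sigma2_p=6956.49, sigma2_e=21192.93, h2=0.10, rep=0.32),
    },
    "gir": {
        "general": dict(sigma2_a=6958.15, sigma2_p=7829.34, sigma2_e=26867.49, h2=0.17, rep=0.35),
        "low": dict(sigma2_a=5870.29, sigma2_p=6942.32, sigma2_e=19476.60, h2=0.18, rep=0.40),
        "high": dict(sigma2_a=9942.05, sigma2_p=8262.16, sigma2_e=30988.95, h2=0.20, rep=0.37),
    },
    "holstein": {
        "general": dict(sigma2_a=4993.91, sigma2_p=6522.89, sigma2_e=29162.51, h2=0.12, rep=0.28),
        "low": dict(sigma2_a=3393.68, sigma2_p=6005.77, sigma2_e=21319.34, h2=0.11, rep=0.31),
        "high": dict(sigma2_a=7202.86, sigma2_p=6737.18, sigma2_e=34589.79, h2=0.15, rep=0.29),
    },
}

GENETIC_CORRELATIONS = {"girolando": 0.88, "gir": 0.85, "holstein": 0.79}

# Girolando permanent-environment variance, high vs low class: +98.36%
PE_CONTRAST_PCT = 98.36


def ratio_checks() -> list[dict]:
    """Recompute h2 and rep from the printed components, per analysis column."""
    rows = []
    for breed, cols in VARIANCE_COMPONENTS.items():
        for analysis, vc in cols.items():
            h2 = heritability(vc["sigma2_a"], vc["sigma2_p"], vc["sigma2_e"])
            rep = repeatability(vc["sigma2_a"], vc["sigma2_p"], vc["sigma2_e"])
            rows.append(
                dict(
                    breed=breed,
                    analysis=analysis,
                    h2_computed=float(h2),
                    h2_printed=vc["h2"],
                    rep_computed=float(rep),
                    rep_printed=vc["rep"],
                )
            )
    return rows


def cv_checks() -> list[dict]:
    """Recompute CV = SD/mean * 100 from the printed descriptive cells."""
    rows = []
    for breed, cols in DESCRIPTIVE.items():
        for analysis, (mean, sd, cv, _nl, _ncg) in cols.items():
            rows.append(
                dict(breed=breed, analysis=analysis, cv_computed=100.0 * sd / mean, cv_printed=cv)
            )
    return rows


def pe_contrast_pct() -> float:
    """Girolando permanent-environment variance, high vs low, in percent."""
    low = VARIANCE_COMPONENTS["girolando"]["low"]["sigma2_p"]
    high = VARIANCE_COMPONENTS["girolando"]["high"]["sigma2_p"]
    return 100.0 * (high - low) / low
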