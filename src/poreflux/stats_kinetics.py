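"""Statistics of contact-conditioned pore diameters and Arrhenius rate ratios.

The contact/no-contact diameter comparison uses the two-sided Wilcoxon
rank-sum test (exact by enumeration for small tie-free samples, otherwise a
tie-corrected normal approximation with continuity correction). Transition
rate ratios assume a constant Kramers/Arrhenius prefactor, so
k_a/k_b = exp(−(ΔG‡_a − ΔG‡_b)/kBT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .potentials import T_DEFAULT, thermal_energy

EXACT_N_MAX = 12  # exact enumeration when n_x + n_y ≤ this and no ties


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (rank-sum statistic of x with midranks, two-sided p). Modes:
    ``exact`` (enumeration), ``normal`` (tie-corrected normal approximation
    with continuity correction), ``auto`` (exact when n_x + n_y ≤ 12 and no
    ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= EXACT_N_MAX and not has_ties) else "normal"
    if mode not in ("exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" and has_ties:
        mode = "normal"  # exact null distribution assumes no ties
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    # rank-sum statistic W = U + n_x(n_x+1)/2
    W = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return W, float(res.pvalue)


def compare_conditioned(
    diameters,
    contacts,
    residues: list[str] | None = None,
    metabolites: list[str] | None = None,
    alpha: float = 0.01,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Contact vs no-contact diameter comparison per (metabolite, residue).

    ``diameters``: pandas Series of per-frame constriction diameters indexed
    by frame (or a dict of such, keyed by metabolite label). ``contacts``: a
    DataFrame with columns (frame, residue, contact) (or a matching dict).
    Rows where either category is empty get no p-value and are flagged
    ``insufficient``. ``adjust='bh'`` applies a Benjamini–Hochberg correction
    (off by default; raw p-values are reported per pair).
    """
    if not isinstance(diameters, dict):
        diameters = {"metabolite": diameters}
        contacts = {"metabolite": contacts}
    if metabolites is None:
        metabolites = list(diameters)
    rows = []
    for met in metabolites:
        diam = diameters[met]
        ct = contacts[met]
        res_list = residues or sorted(ct["residue"].unique())
        for res in res_list:
            sub = ct[ct["residue"] == res]
            missing = set(sub["frame"]) - set(diam.index)
            if missing:
                raise ValueError(
                    f"contact table for {met}/{res} references frames absent "
                    f"from the diameter series (e.g. {sorted(missing)[:3]})"
                )
            merged = sub.set_index("frame").join(diam.rename("diameter"))
            d_c = merged.loc[merged["contact"], "diameter"].to_numpy()
            d_n = merged.loc[~merged["contact"], "diameter"].to_numpy()
            insufficient = d_c.size == 0 or d_n.size == 0
            if insufficient:
                p = np.nan
            else:
                _, p = wilcoxon_rank_sum(d_c, d_n)
            rows.append(
                {
                    "metabolite": met,
                    "residue": res,
                    "n_contact": d_c.size,
                    "n_nocontact": d_n.size,
                    "median_contact": float(np.median(d_c)) if d_c.size else np.nan,
                    "median_nocontact": float(np.median(d_n)) if d_n.size else np.nan,
                    "p": p,
                    "insufficient": insufficient,
                }
            )
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv)
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.clip(ranked, 0.0, 1.0)
        q[ok] = adj
    return q


@dataclass
class ViolinSummary:
    median: float
    q1: float
    q3: float
    grid: np.ndarray | None
    density: np.ndarray | None
    degenerate: bool = False


def violin_summary(values, grid_size: int = 256) -> ViolinSummary:
    """Median, quartiles and a Gaussian-KDE density curve (Silverman rule).

    A constant sample is returned as a flagged degenerate spike with no
    density curve. The density integrates to 1 over the grid within 1%.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    if np.ptp(v) == 0:
        return ViolinSummary(med, q1, q3, None, None, degenerate=True)
    kde = stats.gaussian_kde(v, bw_method="silverman")
    bw = kde.factor * v.std(ddof=1)
    grid = np.linspace(v.min() - 4 * bw, v.max() + 4 * bw, grid_size)
    return ViolinSummary(med, q1, q3, grid, kde(grid))


@dataclass(frozen=True)
class RateRatioResult:
    numerator: str
    denominator: str
    ddG: float  # kcal·mol⁻¹
    T: float  # K
    ratio: float

    def __post_init__(self) -> None:
        expected = float(np.exp(-self.ddG / thermal_energy(self.T)))
        if not np.isclose(self.ratio, expected, rtol=1e-12, atol=0.0):
            raise ValueError("ratio inconsistent with exp(−ΔΔG‡/kBT)")


def rate_ratio(
    dG_a: float,
    dG_b: float,
    T: float = T_DEFAULT,
    label_a: str = "a",
    label_b: str = "b",
) -> RateRatioResult:
    """k_a/k_b = exp(−(ΔG‡_a − ΔG‡_b)/kBT) under a constant prefactor.

    Setting dG_b = 0 reproduces the barrierless-reference construction.
    """
    ddG = dG_a - dG_b
    ratio = float(np.exp(-ddG / thermal_energy(T)))
    return RateRatioResult(
        numerator=label_a, denominator=label_b, ddG=ddG, T=T, ratio=ratio
    )
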