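"""Multivariate group comparison of DMR methylation via Hotelling's T-squared.

A DMR is tested as the vector of its member-CpG beta values.  Two designs:

* two-sample:  T^2 = (n1 n2 / (n1 + n2)) (xbar1 - xbar2)' S_pooled^{-1}
  (xbar1 - xbar2), referred to F(p, n1 + n2 - p - 1) through
  F = (n1 + n2 - p - 1) / (p (n1 + n2 - 2)) * T^2;
* paired: a one-sample T^2 on the within-pair differences,
  T^2 = n dbar' S_d^{-1} dbar, F = (n - p) / (p (n - 1)) * T^2 against
  F(p, n - p).

When the pooled covariance is singular or p exceeds the error degrees of
freedom, the covariance is shrunk toward its diagonal with a
Ledoit-Wolf-style intensity estimated from the data, the F reference is
kept approximately, and the result is flagged ``regularized``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import DMRSet, MethylationMatrix, SampleTable, ValidationError

logger = logging.getLogger(__name__)

_COND_MAX = 1e12


@dataclass
class HotellingResult:
    dmr_id: str
    t_squared: float
    f_statistic: float
    df1: float
    df2: float
    p_value: float
    n1: int
    n2: int  # == n1 for the paired design (number of pairs)
    p_dim: int
    design: str  # "two_sample" | "paired"
    regularized: bool = False
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        if self.t_squared < -1e-10:
            raise ValidationError("T^2 must be non-negative")
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValidationError("p-value must lie in [0, 1]")


def _shrink_intensity(centered: np.ndarray, dof: int) -> float:
    """Ledoit-Wolf-style intensity for shrinking off-diagonal covariances.

    Estimates lambda* = sum_{i != j} Var-hat(s_ij) / sum_{i != j} s_ij^2
    from the centered observations (Schafer-Strimmer diagonal target),
    clipped to [0, 1].
    """
    n = centered.shape[0]
    if n < 2:
        return 1.0
    w = centered[:, :, None] * centered[:, None, :]  # n x p x p products
    s = w.sum(axis=0) / dof
    wbar = w.mean(axis=0)
    var_s = (n / ((n - 1.0) * dof**2 / n)) * ((w - wbar) ** 2).sum(axis=0) / n
    off = ~np.eye(s.shape[0], dtype=bool)
    denom = (s[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    lam = var_s[off].sum() / denom
    return float(np.clip(lam, 0.0, 1.0))


def _solve_spd(s: np.ndarray, diff: np.ndarray, centered: np.ndarray, dof: int,
               regularize: str | bool) -> tuple[np.ndarray, bool, float]:
    """Return S^{-1} d, handling singular/ill-conditioned S by shrinkage."""
    p = s.shape[0]
    needs = dof < p or np.linalg.cond(s) > _COND_MAX
    if not needs:
        try:
            return np.linalg.solve(s, diff), False, 0.0
        except np.linalg.LinAlgError:
            needs = True
    if regularize is False or regularize == "never":
        raise ValidationError(
            "singular or under-determined pooled covariance and regularization disabled"
        )
    lam = _shrink_intensity(centered, dof)
    lam = max(lam, 1e-3)
    target = np.diag(np.diag(s))
    s_shrunk = (1.0 - lam) * s + lam * target
    if not np.all(np.diag(s_shrunk) > 0):
        s_shrunk = s_shrunk + np.eye(p) * (np.trace(s_shrunk) / max(p, 1) * 1e-6 + 1e-12)
    return np.linalg.solve(s_shrunk, diff), True, lam


def hotelling_two_sample(
    x1: np.ndarray, x2: np.ndarray, regularize: str | bool = "auto", dmr_id: str = ""
) -> HotellingResult:
    """Two-sample Hotelling T^2 on complete-case sample x feature matrices."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[1] != x2.shape[1]:
        raise ValidationError("the two groups measure different numbers of variables")
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValidationError("missing entries: drop incomplete samples before testing")
    n1, n2, p = x1.shape[0], x2.shape[0], x1.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 samples")
    dof = n1 + n2 - 2
    if dof < p and (regularize is False or regularize == "never"):
        raise ValidationError(f"p={p} exceeds error df={dof} and shrinkage is disabled")

    diff = x1.mean(axis=0) - x2.mean(axis=0)
    c1 = x1 - x1.mean(axis=0)
    c2 = x2 - x2.mean(axis=0)
    centered = np.vstack([c1, c2])
    s_pooled = (c1.T @ c1 + c2.T @ c2) / dof

    sol, reg, lam = _solve_spd(s_pooled, diff, centered, dof, regularize)
    t2 = float((n1 * n2 / (n1 + n2)) * diff @ sol)
    t2 = max(t2, 0.0)
    df1 = float(p)
    # df2 < 1 only on the regularized path; floor keeps the F reference usable
    df2 = float(max(n1 + n2 - p - 1, 1))
    f = max(float((df2 / (p * dof)) * t2), 0.0)
    p_val = float(sps.f.sf(f, df1, df2))
    return HotellingResult(
        dmr_id, t2, f, df1, df2, p_val, n1, n2, p, "two_sample", reg, lam
    )


def hotelling_paired(
    differences: np.ndarray, regularize: str | bool = "auto", dmr_id: str = ""
) -> HotellingResult:
    """One-sample Hotelling T^2 on a pairs x features matrix of differences."""
    d = np.atleast_2d(np.asarray(differences, dtype=float))
    if np.isnan(d).any():
        raise ValidationError("missing entries: drop incomplete pairs before testing")
    n, p = d.shape
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    dof = n - 1
    if dof < p and (regularize is False or regularize == "never"):
        raise ValidationError(f"p={p} exceeds error df={dof} and shrinkage is disabled")

    dbar = d.mean(axis=0)
    c = d - dbar
    s_d = (c.T @ c) / dof
    sol, reg, lam = _solve_spd(s_d, dbar, c, dof, regularize)
    t2 = max(float(n * dbar @ sol), 0.0)
    df1 = float(p)
    df2 = float(max(n - p, 1))
    f = max(float((df2 / (p * dof)) * t2), 0.0)
    p_val = float(sps.f.sf(f, df1, df2))
    return HotellingResult(dmr_id, t2, f, df1, df2, p_val, n, n, p, "paired", reg, lam)


# ---------------------------------------------------------------------------
# Per-DMR testing over a whole dataset
# ---------------------------------------------------------------------------

def _complete_rows(x: np.ndarray) -> np.ndarray:
    return ~np.isnan(x).any(axis=1)


def group_summary(
    m: MethylationMatrix, d: DMRSet, s: SampleTable, labels: tuple[str, str]
) -> pd.DataFrame:
    """Per-DMR, per-CpG, per-group mean and SD of beta values (long format)."""
    frame = m.to_frame()
    rows = []
    for dmr in d:
        for label in labels:
            cols = s.samples_in_group(label)
            sub = frame.loc[dmr.probe_ids, cols]
            for probe in dmr.probe_ids:
                vals = sub.loc[probe].to_numpy(dtype=float)
                vals = vals[~np.isnan(vals)]
                rows.append(
                    {
                        "dmr_id": dmr.dmr_id,
                        "gene_label": dmr.gene_label,
                        "probe_id": probe,
                        "group": label,
                        "n": int(vals.size),
                        "mean": float(vals.mean()) if vals.size else np.nan,
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def test_all_dmrs(
    m: MethylationMatrix,
    d: DMRSet,
    s: SampleTable,
    groups: tuple[str, str],
    design: str = "auto",
    mt_correction: str = "none",
    regularize: str | bool = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hotelling test per DMR between two sample groups.

    ``design="auto"`` uses the paired form when every sample of both groups
    belongs to a complete pair, else the two-sample form.  Samples (or
    pairs) with any missing CpG within a DMR are dropped for that DMR;
    untestable DMRs are flagged, never silently removed.  Returns the
    results table (one row per DMR, ordered by dmr_id) and the long-format
    per-group mean/SD companion.
    """
    label_a, label_b = groups
    for lbl in groups:
        if not s.samples_in_group(lbl):
            raise ValidationError(f"group label {lbl!r} matches no samples")
    if mt_correction not in ("none", "bonferroni", "bh"):
        raise ValueError("mt_correction must be none, bonferroni or bh")
    d_sorted = DMRSet(sorted(d.dmrs, key=lambda r: r.dmr_id))
    d_sorted.resolve_against(m)
    frame = m.to_frame()

    pairs = s.pairs_between(label_a, label_b)
    if design == "auto":
        paired_samples = {x for ab in pairs for x in ab}
        covered = set(s.samples_in_group(label_a)) | set(s.samples_in_group(label_b))
        if pairs and covered <= paired_samples:
            design = "paired"
        else:
            if pairs:
                logger.info("incomplete pairing; falling back to two-sample design")
            design = "two_sample"
    if design not in ("two_sample", "paired"):
        raise ValueError("design must be two_sample, paired or auto")
    if design == "paired" and not pairs:
        raise ValidationError("paired design requested but no complete pairs found")

    cols_a = s.samples_in_group(label_a)
    cols_b = s.samples_in_group(label_b)
    rows = []
    for dmr in d_sorted:
        sub = frame.loc[dmr.probe_ids]
        base = {
            "dmr_id": dmr.dmr_id,
            "gene_label": dmr.gene_label,
            "p_dim": len(dmr.probe_ids),
            "design": design,
        }
        try:
            if design == "paired":
                da = sub[[a for a, _ in pairs]].to_numpy(dtype=float).T
                db = sub[[b for _, b in pairs]].to_numpy(dtype=float).T
                diffs = da - db
                diffs = diffs[_complete_rows(diffs)]
                if diffs.shape[0] < 3:
                    raise ValidationError("fewer than 3 complete pairs")
                res = hotelling_paired(diffs, regularize, dmr.dmr_id)
            else:
                xa = sub[cols_a].to_numpy(dtype=float).T
                xb = sub[cols_b].to_numpy(dtype=float).T
                xa = xa[_complete_rows(xa)]
                xb = xb[_complete_rows(xb)]
                if xa.shape[0] < 2 or xb.shape[0] < 2:
                    raise ValidationError("fewer than 2 complete samples in a group")
                res = hotelling_two_sample(xa, xb, regularize, dmr.dmr_id)
        except ValidationError as exc:
            rows.append(
                base
                | {
                    "n1": 0, "n2": 0, "t_squared": np.nan, "f": np.nan,
                    "df1": np.nan, "df2": np.nan, "p": np.nan,
                    "regularized": False, "untestable": True, "note": str(exc),
                }
            )
            continue
        rows.append(
            base
            | {
                "n1": res.n1, "n2": res.n2, "t_squared": res.t_squared,
                "f": res.f_statistic, "df1": res.df1, "df2": res.df2,
                "p": res.p_value, "regularized": res.regularized,
                "untestable": False, "note": "",
            }
        )
    results = pd.DataFrame(rows)

    if mt_correction != "none":
        from statsmodels.stats.multitest import multipletests

        ok = results["p"].notna()
        adj = np.full(len(results), np.nan)
        if ok.any():
            method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[mt_correction]
            adj[ok.to_numpy()] = multipletests(results.loc[ok, "p"], method=method)[1]
        results["p_adj"] = adj
    else:
        results["p_adj"] = results["p"]

    summary = group_summary(m, d_sorted, s, groups)
    return results, summary
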