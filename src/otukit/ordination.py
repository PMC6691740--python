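"""PCoA, PERMANOVA, environmental vector fitting and rank-correlation screens."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from otukit.diversity import DistanceMatrix
from otukit.tables_io import SampleMetadata, ValidationError


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray        # samples x positive axes
    eigenvalues: np.ndarray        # all eigenvalues, descending (may be negative)
    proportion_explained: np.ndarray  # per positive axis, vs sum of positive eigenvalues


@dataclass
class PermanovaResult:
    grouping: str
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


@dataclass
class EnvfitResult:
    variable: str
    direction: np.ndarray  # unit vector over the fitted axes
    r2: float
    p_value: float
    n: int


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling via Gower double-centering.

    B = -1/2 J D^2 J; coordinates are eigenvectors scaled by sqrt(eigenvalue)
    for positive eigenvalues only. Negative eigenvalues are reported
    unaltered; proportion explained is relative to the positive part.
    """
    n = len(d.sample_ids)
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    d2 = d.matrix**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-9 * abs(eigvals[0])) if eigvals[0] > 0 else eigvals > 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return OrdinationResult(list(d.sample_ids), coords, eigvals, prop)


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * len(idx))
    return ss


def permanova(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    grouping_name: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA with an add-one permutation p-value.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)) from squared
    distances; p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    labels = np.asarray(list(groups))
    n = len(d.sample_ids)
    if labels.shape[0] != n:
        raise ValidationError("group labels do not match distance matrix")
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        small = levels[counts < 2]
        raise ValidationError(f"groups with fewer than 2 samples: {list(small)}")
    k = len(levels)
    d2 = d.matrix**2
    ss_total = d2.sum() / (2.0 * n)

    def f_stat(lab: np.ndarray) -> float:
        ss_w = _ss_within(d2, lab)
        ss_b = ss_total - ss_w
        return (ss_b / (k - 1)) / (ss_w / (n - k))

    f_obs = f_stat(labels)
    r2 = 1.0 - _ss_within(d2, labels) / ss_total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if f_stat(rng.permutation(labels)) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(grouping_name, float(f_obs), float(r2), float(p), n_permutations)


def permanova_exhaustive(d: DistanceMatrix, groups) -> PermanovaResult:
    """Exact p over every distinct label assignment (small n only)."""
    from itertools import permutations

    labels = np.asarray(list(groups))
    n = len(labels)
    if n > 10:
        raise ValidationError("exhaustive enumeration is limited to n <= 10")
    levels, counts = np.unique(labels, return_counts=True)
    k = len(levels)
    d2 = d.matrix**2
    ss_total = d2.sum() / (2.0 * n)

    def f_stat(lab) -> float:
        ss_w = _ss_within(d2, np.asarray(lab))
        return ((ss_total - ss_w) / (k - 1)) / (ss_w / (n - k))

    f_obs = f_stat(labels)
    seen = set()
    f_all = []
    for perm in permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        f_all.append(f_stat(perm))
    f_all = np.array(f_all)
    p = float((f_all >= f_obs - 1e-12).mean())
    r2 = 1.0 - _ss_within(d2, labels) / ss_total
    return PermanovaResult("exhaustive", float(f_obs), float(r2), p, len(f_all))


def envfit(
    ordination: OrdinationResult,
    values: np.ndarray,
    variable: str = "variable",
    k_axes: int = 2,
    n_permutations: int = 999,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> EnvfitResult:
    """Fit one numeric variable onto the first ``k_axes`` ordination axes.

    R2 is the coefficient of determination of the least-squares regression
    of the variable on the axis scores; the direction is the unit vector of
    fitted coefficients; p is a permutation tail probability of R2 under
    shuffling of the variable.
    """
    values = np.asarray(values, dtype=float)
    if sample_ids is not None:
        idx = [ordination.sample_ids.index(s) for s in sample_ids]
        scores = ordination.coordinates[idx, :]
    else:
        scores = ordination.coordinates
    if values.shape[0] != scores.shape[0]:
        raise ValidationError("variable length does not match ordination samples")
    if np.ptp(values) == 0:
        raise ValidationError(f"variable {variable!r} is constant")
    k = min(k_axes, scores.shape[1])
    x = scores[:, :k]
    xc = x - x.mean(axis=0)

    def fit_r2(y: np.ndarray) -> tuple[float, np.ndarray]:
        yc = y - y.mean()
        coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        resid = yc - xc @ coef
        tss = float(yc @ yc)
        return 1.0 - float(resid @ resid) / tss, coef

    r2_obs, coef = fit_r2(values)
    norm = np.linalg.norm(coef)
    direction = coef / norm if norm > 0 else coef
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if fit_r2(rng.permutation(values))[0] >= r2_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return EnvfitResult(variable, direction, float(r2_obs), float(p), len(values))


def spearman_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with midranks; two-sided p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def rank_correlation_screen(
    alpha: pd.DataFrame,
    meta: SampleMetadata,
    variables: list[str],
    alpha_column: str = "shannon",
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of an alpha-diversity index against each factor.

    Samples with NA for a factor are dropped for that factor only; factors
    with fewer than 4 paired observations yield NA with a warning column.
    """
    records = []
    for var in variables:
        ids, vals = meta.variable(var, [s for s in alpha.index if s in meta.frame.index])
        ids = [s for s in ids if s in alpha.index]
        y = alpha.loc[ids, alpha_column].to_numpy(dtype=float)
        x = meta.frame.loc[ids, var].to_numpy(dtype=float)
        if len(ids) < 4:
            records.append({"variable": var, "n": len(ids), "rho": np.nan, "p_value": np.nan,
                            "note": "fewer than 4 paired observations"})
            continue
        rho, p = spearman_rank(x, y)
        records.append({"variable": var, "n": len(ids), "rho": rho, "p_value": p, "note": ""})
    df = pd.DataFrame(records).set_index("variable")
    if adjust:
        from otukit.indicators import benjamini_hochberg

        ok = df["p_value"].notna()
        q = np.full(len(df), np.nan)
        q[ok.to_numpy()] = benjamini_hochberg(df.loc[ok, "p_value"].to_numpy())
        df["q_value"] = q
    return df
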