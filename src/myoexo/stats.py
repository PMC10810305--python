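"""Scalar and curve-level hypothesis tests, and the paired-t power analysis.

Scalar outcomes (per-condition RMS values) get a one-way ANOVA — classical
or repeated-measures — with Tukey HSD post-hocs when the omnibus test is
significant.  Curve outcomes (101-point gait-cycle means per subject) get
one-dimensional statistical parametric mapping with permutation inference:
the pointwise F curve is compared against the permutation distribution of
its maximum, which controls the family-wise error over the whole cycle
without distributional assumptions, and suprathreshold clusters receive
cluster-mass permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .signals import CYCLE_GRID


@dataclass
class ScalarTestResult:
    F: float
    df: tuple[int, int]
    p: float
    posthoc: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)
    kind: str = "oneway"


@dataclass
class SPMResult:
    """Pointwise F curve with max-statistic permutation inference."""

    F_curve: np.ndarray
    threshold: float
    clusters: list[tuple[float, float, float]]  # (%cycle start, end, cluster p)
    p_max: float
    n_perm: int

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for k, v in out.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least two values")
    return out


def oneway_anova(
    groups: Mapping[str, Sequence[float]],
    repeated_measures: bool = False,
    alpha: float = 0.05,
) -> ScalarTestResult:
    """One-way ANOVA across conditions, with Tukey HSD when significant.

    The repeated-measures variant treats equally indexed values across
    groups as the same subject (all groups must then be the same length).
    """
    g = _as_groups(groups)
    names = list(g)
    if repeated_measures:
        sizes = {v.size for v in g.values()}
        if len(sizes) != 1:
            raise ValueError("repeated-measures ANOVA needs equal group sizes")
        n = sizes.pop()
        long = pd.DataFrame({
            "value": np.concatenate([g[k] for k in names]),
            "cond": np.repeat(names, n),
            "subject": np.tile(np.arange(n), len(names)),
        })
        from statsmodels.stats.anova import AnovaRM

        res = AnovaRM(long, "value", "subject", within=["cond"]).fit()
        row = res.anova_table.iloc[0]
        F, p = float(row["F Value"]), float(row["Pr > F"])
        df = (int(row["Num DF"]), int(row["Den DF"]))
        kind = "repeated_measures"
    else:
        F, p = sstats.f_oneway(*[g[k] for k in names])
        F, p = float(F), float(p)
        k = len(names)
        ntot = sum(v.size for v in g.values())
        df = (k - 1, ntot - k)
        kind = "oneway"
    posthoc = tukey_hsd(g) if p < alpha else []
    return ScalarTestResult(F=F, df=df, p=p, posthoc=posthoc, kind=kind)


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
) -> list[tuple[tuple[str, str], float, float]]:
    """All pairwise mean comparisons with studentized-range adjusted p."""
    g = _as_groups(groups)
    names = list(g)
    res = sstats.tukey_hsd(*[g[k] for k in names])
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out.append((
                (names[i], names[j]),
                float(g[names[i]].mean() - g[names[j]].mean()),
                float(res.pvalue[i, j]),
            ))
    return out


def _pointwise_f(data: np.ndarray) -> np.ndarray:
    """Classical one-way F at every grid point; data is (k, n, P)."""
    k, n, _ = data.shape
    gm = data.mean(axis=(0, 1))
    m = data.mean(axis=1)
    ssb = n * ((m - gm) ** 2).sum(axis=0)
    ssw = ((data - m[:, None, :]) ** 2).sum(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (k * (n - 1)))
    return np.where(np.isfinite(f), f, 0.0)


def spm_anova_permutation(
    ensembles: Mapping[str, np.ndarray],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    within_subject: bool = True,
) -> SPMResult:
    """One-way ANOVA along the gait cycle with max-F permutation inference.

    ``ensembles`` maps condition name to an (n_subjects, 101) array of
    subject-mean curves; subjects must be aligned by row across conditions.
    Condition labels are permuted within subject (or freely when
    ``within_subject=False``), the family-wise threshold is the 1-alpha
    quantile of the permuted max-F, and p-values use (b+1)/(n_perm+1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mats = [np.atleast_2d(np.asarray(v, float)) for v in ensembles.values()]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError("all conditions must share (n_subjects, n_points) shape")
    data = np.stack(mats)  # (k, n, P)
    k, n, P = data.shape
    rng = np.random.default_rng(seed)

    f_obs = _pointwise_f(data)
    obs_max = float(f_obs.max())

    if within_subject:
        # independent label permutation per subject
        idx = rng.permuted(
            np.broadcast_to(np.arange(k), (n_perm, n, k)).copy(), axis=2
        ).transpose(0, 2, 1)  # (n_perm, k, n)
        perm_data = data[idx, np.arange(n)[None, None, :], :]
    else:
        flat = data.reshape(k * n, P)
        idx = rng.permuted(
            np.broadcast_to(np.arange(k * n), (n_perm, k * n)).copy(), axis=1
        )
        perm_data = flat[idx].reshape(n_perm, k, n, P)

    # vectorized pointwise F over all permutations
    gm = perm_data.mean(axis=(1, 2), keepdims=True)
    m = perm_data.mean(axis=2, keepdims=True)
    ssb = (n * (m - gm) ** 2).sum(axis=(1, 2))
    ssw = ((perm_data - m) ** 2).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb / (k - 1)) / (ssw / (k * (n - 1)))
    f_perm = np.where(np.isfinite(f_perm), f_perm, 0.0)  # (n_perm, P)
    max_null = f_perm.max(axis=1)

    p_max = (np.count_nonzero(max_null >= obs_max) + 1) / (n_perm + 1)
    threshold = float(np.quantile(max_null, 1.0 - alpha, method="higher"))

    clusters: list[tuple[float, float, float]] = []
    above = f_obs > threshold
    if above.any():
        # maximal runs above threshold, cluster-mass permutation p
        null_mass = _max_cluster_mass(f_perm, threshold)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            mass = float((f_obs[s:e] - threshold).sum())
            p_cl = (np.count_nonzero(null_mass >= mass) + 1) / (n_perm + 1)
            clusters.append((float(CYCLE_GRID[s]), float(CYCLE_GRID[e - 1]), p_cl))
    return SPMResult(F_curve=f_obs, threshold=threshold, clusters=clusters,
                     p_max=float(p_max), n_perm=n_perm)


def _max_cluster_mass(f_perm: np.ndarray, threshold: float) -> np.ndarray:
    """Largest suprathreshold cluster mass per permutation (0 when none)."""
    excess = np.clip(f_perm - threshold, 0.0, None)
    out = np.zeros(f_perm.shape[0])
    for i, row in enumerate(excess):
        if not row.any():
            continue
        above = row > 0
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        out[i] = max(row[s:e].sum() for s, e in zip(edges[::2], edges[1::2]))
    return out


def paired_t_power(n: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a paired t-test at sample size n and effect size d."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        tcrit = sstats.t.ppf(1 - alpha / 2, df)
        return float(1 - sstats.nct.cdf(tcrit, df, nc) + sstats.nct.cdf(-tcrit, df, nc))
    tcrit = sstats.t.ppf(1 - alpha, df)
    return float(1 - sstats.nct.cdf(tcrit, df, nc))


def paired_t_sample_size(
    d: float, alpha: float = 0.05, power: float = 0.8, tails: int = 2, n_max: int = 100000
) -> int:
    """Smallest n whose paired-t (noncentral-t) power reaches the target."""
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < alpha < 1 or not alpha < power < 1:
        raise ValueError("need 0 < alpha < power < 1")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    for n in range(2, n_max + 1):
        if paired_t_power(n, d, alpha, tails) >= power:
            return n
    raise ValueError(f"no n <= {n_max} reaches the requested power")
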