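"""Nonparametric group comparisons with compact letter display.

The measurement distributions produced by the imaging pipeline (well-level
AAI, per-cell intensities, puncta densities) are generally non-normal, so the
comparison workflow is: screen normality with a Lilliefors test
(Kolmogorov-Smirnov with estimated mean and SD, Monte-Carlo p-value), run a
Kruskal-Wallis omnibus test across conditions, follow up with pairwise
rank tests under Bonferroni correction, and summarise the pairwise outcome as
a compact letter display — groups that do not share a letter differ
significantly.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError


@dataclass
class GroupData:
    group_label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValidationError(
                f"group {self.group_label!r} needs n >= 2, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"group {self.group_label!r} has non-finite values")


@dataclass
class ComparisonResult:
    H: float
    p_omnibus: float
    pairwise_p: np.ndarray  # (k, k) Bonferroni-adjusted, diag = 1
    letters: dict[str, str]
    alpha: float
    group_labels: list[str] = field(default_factory=list)


def _as_groups(groups) -> list[GroupData]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupData):
            out.append(g)
        else:
            out.append(GroupData(group_label=f"group{i + 1}", values=np.asarray(g)))
    return out


def lilliefors_test(values, n_mc: int = 10000, seed: int | None = None):
    """Lilliefors normality test with a seeded Monte-Carlo null.

    The statistic is the KS distance between the sample and a normal with the
    sample mean and SD. The p-value is estimated from ``n_mc`` standard-normal
    samples of the same size (each standardized the same way), as
    ``(1 + #{D* >= D}) / (n_mc + 1)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValidationError(f"Lilliefors test needs n >= 4, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("constant sample: normality test undefined")

    def ks_stat(rows: np.ndarray) -> np.ndarray:
        # rows: (m, n); standardize each row by its own mean/SD (ddof=1)
        z = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(
            axis=1, ddof=1, keepdims=True
        )
        z.sort(axis=1)
        cdf = sps.norm.cdf(z)
        n = rows.shape[1]
        grid = np.arange(1, n + 1) / n
        d_plus = (grid - cdf).max(axis=1)
        d_minus = (cdf - (np.arange(n) / n)).max(axis=1)
        return np.maximum(d_plus, d_minus)

    d_obs = float(ks_stat(x[None, :])[0])
    rng = np.random.default_rng(seed)
    null = ks_stat(rng.standard_normal((n_mc, x.size)))
    p = (1.0 + np.count_nonzero(null >= d_obs)) / (n_mc + 1.0)
    return d_obs, float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank tie correction) and chi-square p-value."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    if sum(g.values.size for g in gs) < 3:
        raise ValidationError("Kruskal-Wallis needs total n >= 3")
    h, p = sps.kruskal(*[g.values for g in gs])
    return float(h), float(p)


def pairwise_posthoc(
    groups, alpha: float = 0.05, method: str = "mannwhitney"
) -> np.ndarray:
    """Bonferroni-adjusted pairwise p-values, as a symmetric (k, k) matrix.

    ``method="mannwhitney"`` runs two-sided Mann-Whitney U tests per pair;
    ``method="dunn"`` runs Dunn's z-tests on the pooled midranks (with tie
    correction). The Bonferroni multiplier is the number of pairs,
    k(k-1)/2, and adjusted p-values are capped at 1.
    """
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValidationError("need >= 2 groups")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    n_pairs = k * (k - 1) // 2
    out = np.ones((k, k))
    if method == "dunn":
        pooled = np.concatenate([g.values for g in gs])
        ranks = sps.rankdata(pooled)
        n = pooled.size
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
        splits = np.cumsum([g.values.size for g in gs])[:-1]
        group_ranks = np.split(ranks, splits)
        mean_ranks = [r.mean() for r in group_ranks]
    for i, j in itertools.combinations(range(k), 2):
        if method == "mannwhitney":
            _, raw = sps.mannwhitneyu(
                gs[i].values, gs[j].values, alternative="two-sided"
            )
        elif method == "dunn":
            ni, nj = gs[i].values.size, gs[j].values.size
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            raw = 2.0 * sps.norm.sf(abs(z))
        else:
            raise ValidationError(f"unknown posthoc method {method!r}")
        adj = min(1.0, raw * n_pairs)
        out[i, j] = out[j, i] = adj
    return out


def compact_letter_display(
    significant: np.ndarray, labels: list[str] | None = None
) -> dict[str, str]:
    """Letters per group such that two groups share a letter iff not significant.

    ``significant`` is a symmetric boolean (k, k) matrix (True = the pair
    differs). Uses the insert-and-absorb algorithm: start from one letter
    covering all groups, split it on each significant pair, absorb redundant
    letters, and give any uncovered group its own letter. Minimal letter
    count is not guaranteed; the share-iff-nonsignificant property is.
    """
    sig = np.asarray(significant, dtype=bool)
    if sig.ndim != 2 or sig.shape[0] != sig.shape[1]:
        raise ValidationError("significance matrix must be square")
    if not np.array_equal(sig, sig.T):
        raise ValidationError("significance matrix must be symmetric")
    k = sig.shape[0]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValidationError("labels length does not match matrix size")

    letters: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for cls in [c for c in letters if i in c and j in c]:
            letters.remove(cls)
            for dropped in (i, j):
                new = cls - {dropped}
                if new and not any(new <= other for other in letters):
                    letters.append(new)
        # absorb: drop letters fully contained in another
        letters = [
            c for c in letters if not any(c < other for other in letters)
        ]
    covered = set().union(*letters) if letters else set()
    for g in range(k):
        if g not in covered:
            letters.append({g})

    # verify the defining property before returning
    share = np.zeros((k, k), dtype=bool)
    for cls in letters:
        for i, j in itertools.combinations(sorted(cls), 2):
            share[i, j] = share[j, i] = True
    for i, j in itertools.combinations(range(k), 2):
        if share[i, j] == bool(sig[i, j]):
            raise AssertionError(
                "letter display violates share-iff-nonsignificant "
                f"for pair ({i}, {j})"
            )

    # stable letter order: by smallest member group
    letters.sort(key=lambda c: sorted(c))
    alphabet = string.ascii_lowercase
    if len(letters) > len(alphabet):
        raise ValidationError("more than 26 letters required")
    out = {lab: "" for lab in labels}
    for idx, cls in enumerate(letters):
        for g in sorted(cls):
            out[labels[g]] += alphabet[idx]
    return out


def compare_groups(
    groups, alpha: float = 0.05, method: str = "mannwhitney"
) -> ComparisonResult:
    """Omnibus Kruskal-Wallis + Bonferroni post hocs + compact letter display."""
    gs = _as_groups(groups)
    h, p = kruskal_wallis(gs)
    pmat = pairwise_posthoc(gs, alpha=alpha, method=method)
    labels = [g.group_label for g in gs]
    letters = compact_letter_display(pmat < alpha, labels)
    return ComparisonResult(
        H=h,
        p_omnibus=p,
        pairwise_p=pmat,
        letters=letters,
        alpha=alpha,
        group_labels=labels,
    )
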