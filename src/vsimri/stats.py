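"""Three-group comparison with a normality-gated decision tree.

Each parameter is compared across groups as follows: Shapiro-Wilk normality
per group; if every group looks normal (p > alpha) a one-way ANOVA is the
omnibus test, followed by Tukey's HSD when significant; otherwise the
Kruskal-Wallis test is used, followed by Dunn's test with Bonferroni
correction over the pairs. Significance level alpha = 0.05 throughout, and
no correction is applied across parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["PairwiseResult", "GroupComparison", "compare_groups", "dunn_bonferroni"]


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_adjusted: float
    method: str


@dataclass
class GroupComparison:
    """Results object for one parameter's three-group comparison."""

    parameter: str
    groups: dict[str, np.ndarray]
    normality_p: dict[str, float]
    all_normal: bool
    omnibus_test: str  # "ANOVA" or "Kruskal-Wallis"
    statistic: float
    pvalue: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.pvalue <= self.alpha

    def summary(self) -> str:
        lines = [
            f"Group comparison: {self.parameter or '(unnamed parameter)'}",
            f"  groups: "
            + ", ".join(f"{k} (n={len(v)})" for k, v in self.groups.items()),
            "  Shapiro-Wilk p: "
            + ", ".join(f"{k}={p:.4g}" for k, p in self.normality_p.items()),
            f"  omnibus: {self.omnibus_test}  stat={self.statistic:.4g}  "
            f"p={self.pvalue:.4g}"
            + ("  (significant)" if self.significant else ""),
        ]
        for pw in self.pairwise:
            lines.append(
                f"    {pw.pair[0]} vs {pw.pair[1]}: {pw.method} "
                f"adj. p={pw.p_adjusted:.4g}"
            )
        for note in self.notes:
            lines.append(f"  note: {note}")
        return "\n".join(lines)


def _shapiro_gate(groups: dict[str, np.ndarray], alpha: float):
    """Per-group Shapiro-Wilk p-values; constant groups route to the
    nonparametric branch with a note."""
    pvals: dict[str, float] = {}
    notes: list[str] = []
    all_normal = True
    for label, x in groups.items():
        if np.ptp(x) == 0:
            pvals[label] = float("nan")
            all_normal = False
            notes.append(
                f"group '{label}' is constant; Shapiro-Wilk undefined, "
                "routed to Kruskal-Wallis"
            )
            continue
        p = float(sps.shapiro(x).pvalue)
        pvals[label] = p
        if p <= alpha:
            all_normal = False
    return pvals, all_normal, notes


def dunn_bonferroni(
    groups: dict[str, np.ndarray],
) -> list[PairwiseResult]:
    """Dunn's post-hoc test for all pairs, Bonferroni-adjusted.

    z-statistics use the tie-corrected rank variance
    ``N(N+1)/12 - sum(t^3 - t) / (12 (N - 1))``; adjusted p-values are
    ``min(1, m * p_raw)`` with m the number of pairs.
    """
    labels = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # mean rank per group
    mean_ranks = {}
    start = 0
    for label, x in zip(labels, values):
        mean_ranks[label] = ranks[start : start + x.size].mean()
        start += x.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        na, nb = groups[a].size if hasattr(groups[a], "size") else len(groups[a]), len(
            groups[b]
        )
        se = np.sqrt(variance * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out.append(
            PairwiseResult(
                pair=(a, b),
                statistic=float(z),
                p_adjusted=float(min(1.0, m * p_raw)),
                method="Dunn-Bonferroni",
            )
        )
    return out


def _tukey(groups: dict[str, np.ndarray]) -> list[PairwiseResult]:
    labels = list(groups)
    res = sps.tukey_hsd(*(groups[k] for k in labels))
    out = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        out.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                statistic=float(res.statistic[i, j]),
                p_adjusted=float(res.pvalue[i, j]),
                method="Tukey HSD",
            )
        )
    return out


def compare_groups(
    groups: dict[str, "np.ndarray | list[float]"],
    alpha: float = 0.05,
    parameter: str = "",
) -> GroupComparison:
    """Run the normality-gated three-group comparison for one parameter.

    Requires at least 3 groups with at least 3 observations each. Post-hoc
    pairwise tests are run only when the omnibus test is significant at
    ``alpha``.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, x in groups.items():
        if x.size < 3:
            raise ValueError(f"group '{label}' has {x.size} < 3 observations")

    normality_p, all_normal, notes = _shapiro_gate(groups, alpha)
    values = list(groups.values())
    if all_normal:
        stat, p = sps.f_oneway(*values)
        test = "ANOVA"
    else:
        if all(np.ptp(x) == 0 for x in values) and len(
            {x[0] for x in values}
        ) == 1:
            # all observations identical: no variation to test
            stat, p = float("nan"), 1.0
            notes.append("all groups identical; omnibus test degenerate")
        else:
            stat, p = sps.kruskal(*values)
        test = "Kruskal-Wallis"

    result = GroupComparison(
        parameter=parameter,
        groups=groups,
        normality_p=normality_p,
        all_normal=all_normal,
        omnibus_test=test,
        statistic=float(stat),
        pvalue=float(p),
        alpha=alpha,
        notes=notes,
    )
    if result.significant:
        result.pairwise = _tukey(groups) if test == "ANOVA" else dunn_bonferroni(groups)
    return result
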