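"""Quantitative link between per-codon misreading and assay readouts.

The incorporation model is first order in the per-event misreading
probability epsilon: every cognate codon of the labelled amino acid X
incorporates one label, and every near-cognate codon of X independently
incorporates one label with probability epsilon.  For a reporter with
counts (C_A, NC_A, C_B, NC_B) the expected labelled-residue counts per
molecule are

    E[A] = C_A + eps * NC_A        E[B] = C_B + eps * NC_B

and the observable, normalised so that an error-free ribosome reads 1, is

    f(eps) = (E[A] / E[B]) / (C_A / C_B).

f is strictly increasing in eps exactly when NC_A/C_A > NC_B/C_B, with
initial slope NC_A/C_A - NC_B/C_B — which is why a high-discrimination
CDS (MT-CO1: slope 94.5) responds to misreading that leaves a low one
(MT-CO2: slope 2.95) flat.  A per-molecule Monte Carlo simulator, the
inverse problem (epsilon from an observed fold change) and the
dual-reporter replicate normalisation used by gain-of-function luciferase
assays complete the toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats as sstats

from .near_cognate import CodonNeighborhood, count_codons
from .reporter import ReporterStats
from .seqio import CodingSequence


@dataclass(frozen=True)
class MisreadingModelParams:
    """Parameters of the per-molecule incorporation simulator."""

    epsilon: float
    rho: float = 0.0
    n_molecules: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


@dataclass(frozen=True)
class IncorporationResult:
    """Expected (or simulated) label incorporation per molecule."""

    mean_count_A: float
    mean_count_B: float
    ratio_fold_change: float | None
    mc_stderr: float
    flag: str = "defined"


def expected_ratio_fold_change(stats: ReporterStats, epsilon: float) -> IncorporationResult:
    """Closed-form fold change of the label ratio at misreading level epsilon."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    mean_a = stats.C_A + epsilon * stats.NC_A
    mean_b = stats.C_B + epsilon * stats.NC_B
    if stats.C_A == 0 or stats.C_B == 0:
        return IncorporationResult(mean_a, mean_b, None, 0.0, flag="undefined")
    fold = (mean_a / mean_b) / (stats.C_A / stats.C_B)
    return IncorporationResult(mean_a, mean_b, fold, 0.0)


def ratio_slope_at_zero(stats: ReporterStats) -> float:
    """d f / d eps at eps = 0: NC_A/C_A - NC_B/C_B (reporter sensitivity)."""
    if stats.C_A == 0 or stats.C_B == 0:
        raise ValueError("slope undefined for zero cognate counts")
    return stats.NC_A / stats.C_A - stats.NC_B / stats.C_B


def simulate_incorporation(
    cds: CodingSequence,
    hood_a: CodonNeighborhood,
    hood_b: CodonNeighborhood,
    params: MisreadingModelParams,
) -> IncorporationResult:
    """Per-molecule Monte Carlo counterpart of the closed form.

    Each of ``n_molecules`` molecules incorporates one label at every
    cognate codon and, independently with probability epsilon, one label
    at every near-cognate codon.  Fully reproducible given the seed.
    """
    c_a, nc_a = count_codons(cds, hood_a)
    c_b, nc_b = count_codons(cds, hood_b)
    rng = np.random.default_rng(params.seed)
    n = params.n_molecules
    counts_a = c_a + rng.binomial(nc_a, params.epsilon, size=n)
    counts_b = c_b + rng.binomial(nc_b, params.epsilon, size=n)
    mean_a = float(counts_a.mean())
    mean_b = float(counts_b.mean())
    if c_a == 0 or c_b == 0 or mean_b == 0:
        return IncorporationResult(mean_a, mean_b, None, 0.0, flag="undefined")
    fold = (mean_a / mean_b) / (c_a / c_b)
    # delta-method standard error of the ratio of sample means
    var_a = float(counts_a.var(ddof=1)) if n > 1 else 0.0
    var_b = float(counts_b.var(ddof=1)) if n > 1 else 0.0
    se_ratio = np.sqrt(
        (var_a / mean_b**2 + mean_a**2 * var_b / mean_b**4) / n
    )
    return IncorporationResult(mean_a, mean_b, fold, float(se_ratio * (c_b / c_a)))


def fit_epsilon(observed_fold_change: float, stats: ReporterStats) -> float:
    """Invert the closed-form model: the epsilon giving the observed fold change.

    Requires a sensitive reporter (positive slope NC_A/C_A - NC_B/C_B) and
    an observation within [f(0), f(1)] = [1, f(1)].  Solved by a bracketed
    root search on [0, 1] to |delta eps| < 1e-12.
    """
    if ratio_slope_at_zero(stats) <= 0:
        raise ValueError("reporter has non-positive sensitivity; epsilon not identifiable")
    f_max = expected_ratio_fold_change(stats, 1.0).ratio_fold_change
    if not 1.0 <= observed_fold_change <= f_max:
        raise ValueError(
            f"observed fold change {observed_fold_change} outside model range [1, {f_max:.4g}]"
        )
    if observed_fold_change == 1.0:
        return 0.0

    def g(eps: float) -> float:
        return expected_ratio_fold_change(stats, eps).ratio_fold_change - observed_fold_change

    return float(optimize.brentq(g, 0.0, 1.0, xtol=1e-12, rtol=8.9e-16))


@dataclass(frozen=True)
class DualReporterMeasurement:
    """One replicate of a dual-reporter (e.g. firefly/Renilla) assay."""

    test_signal: float
    reference_signal: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.test_signal <= 0 or self.reference_signal <= 0:
            raise ValueError("signals must be positive")

    @property
    def ratio(self) -> float:
        return self.test_signal / self.reference_signal


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class NormalizedFoldChange:
    """Mutant-over-wild-type normalisation of dual-reporter ratios.

    The reference (wild-type) group's normalised mean is 1 by
    construction; ``fold_change`` is the test group's mean ratio on that
    scale.
    """

    fold_change: float
    test: GroupSummary
    reference: GroupSummary


def _summary(ratios: np.ndarray, scale: float) -> GroupSummary:
    scaled = ratios / scale
    n = scaled.size
    sem = float(scaled.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GroupSummary(float(scaled.mean()), sem, n)


def normalize_dual_reporter(
    test_group: Sequence[DualReporterMeasurement],
    reference_group: Sequence[DualReporterMeasurement],
) -> NormalizedFoldChange:
    """Normalise test-group signal ratios to the reference group.

    Per replicate the test/reference signal ratio is formed; the fold
    change is the mean of test ratios over the mean of reference ratios
    (mean of ratios, matching per-sample normalisation of the assay).
    """
    if not test_group or not reference_group:
        raise ValueError("both groups need at least one replicate")
    t = np.array([m.ratio for m in test_group], dtype=float)
    r = np.array([m.ratio for m in reference_group], dtype=float)
    scale = float(r.mean())
    return NormalizedFoldChange(
        fold_change=float(t.mean() / scale),
        test=_summary(t, scale),
        reference=_summary(r, scale),
    )


def group_difference_test(
    test_group: Sequence[DualReporterMeasurement],
    reference_group: Sequence[DualReporterMeasurement],
    welch: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample t test on the replicate ratios.

    Welch's correction for unequal variances is on by default.  Returns
    ``(t_statistic, p_value)``.
    """
    t = [m.ratio for m in test_group]
    r = [m.ratio for m in reference_group]
    res = sstats.ttest_ind(t, r, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
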