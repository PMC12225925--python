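"""Paired permutation inference for landing-count experiments.

Each trial pairs a treatment flower with a simultaneously observed Paired
Control (an identically rigged flower whose electrode is electrically
floating). The test statistic is the mean over trials of
``control_count - treatment_count``; a positive value means the treatment
suppressed landings. The null distribution is built by resampling the
treatment/control labels and recomputing the statistic:

* ``signflip`` — labels are swapped independently within each pair
  (equivalently, each paired difference is negated) with probability 1/2.
  This is the paired test proper; for small n it can also be enumerated
  exhaustively over all 2**n sign assignments.
* ``full_relabel`` — all 2n counts are pooled and randomly re-partitioned
  into two groups of n, ignoring the pairing.

The two-sided p-value is the plain proportion of resampled statistics whose
magnitude matches or exceeds the observed magnitude (ties count as
exceedances; the observed arrangement is not appended to the null).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedTrial",
    "PermutationResult",
    "DiagnosticsReport",
    "observed_statistic",
    "permutation_null",
    "exhaustive_signflip_null",
    "p_value",
    "null_summary",
    "effect_size",
    "median_reduction",
    "distribution_diagnostics",
    "paired_permutation_test",
    "pairs_from_frame",
    "read_pairs_csv",
]

SCHEMES = ("signflip", "full_relabel")

#: magnitude tolerance when counting ties between |null| and |observed|,
#: guarding against float error in means of integer counts
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class PairedTrial:
    """Landing counts for one two-hour treatment/Paired-Control observation."""

    trial_id: int
    treatment_count: int
    control_count: int

    def __post_init__(self) -> None:
        if self.treatment_count < 0 or self.control_count < 0:
            raise ValueError(
                f"trial {self.trial_id}: landing counts must be non-negative, got "
                f"treatment={self.treatment_count}, control={self.control_count}"
            )

    @property
    def difference(self) -> int:
        """Per-pair statistic contribution: control - treatment."""
        return self.control_count - self.treatment_count


@dataclass
class PermutationResult:
    """Full record of one paired permutation test."""

    observed_difference: float
    p_value: float
    null_mean: float
    null_sd: float
    null_interval: tuple[float, float]
    effect_size: float
    effect_size_kind: str
    n_permutations: int
    scheme: str
    seed: int | None
    n_pairs: int
    exact: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["null_interval"] = list(self.null_interval)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _as_diff_array(pairs: Sequence[PairedTrial]) -> np.ndarray:
    if len(pairs) == 0:
        raise ValueError("at least one treatment/control pair is required")
    return np.array([p.difference for p in pairs], dtype=float)


def observed_statistic(pairs: Sequence[PairedTrial]) -> float:
    """Mean over pairs of (control_count - treatment_count), in landings."""
    return float(_as_diff_array(pairs).mean())


def permutation_null(
    pairs: Sequence[PairedTrial],
    n_permutations: int,
    scheme: str = "signflip",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Resampled null distribution of the paired-difference statistic.

    Parameters
    ----------
    pairs
        Observed treatment/control pairs.
    n_permutations
        Number of resampled label assignments (>= 1).
    scheme
        ``"signflip"`` swaps labels within each pair; ``"full_relabel"``
        re-partitions all 2n counts into two groups of n.
    seed
        Seed or ``numpy.random.Generator``; fixed seed gives an identical
        null vector on repeated calls.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid schemes: {SCHEMES}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(pairs)
    if scheme == "signflip":
        diffs = _as_diff_array(pairs)
        signs = rng.integers(0, 2, size=(n_permutations, n)) * 2 - 1
        return (signs * diffs).mean(axis=1)
    # full_relabel: pool all counts, draw n of 2n for the "control" group
    counts = np.array(
        [p.control_count for p in pairs] + [p.treatment_count for p in pairs],
        dtype=float,
    )
    if n == 0:
        raise ValueError("at least one treatment/control pair is required")
    order = np.argsort(rng.random((n_permutations, 2 * n)), axis=1)
    shuffled = counts[order]
    return shuffled[:, :n].mean(axis=1) - shuffled[:, n:].mean(axis=1)


def exhaustive_signflip_null(pairs: Sequence[PairedTrial]) -> np.ndarray:
    """All 2**n sign-assignment statistics (exact signflip null, n <= 20)."""
    diffs = _as_diff_array(pairs)
    n = diffs.size
    if n > 20:
        raise ValueError(f"exhaustive enumeration limited to 20 pairs, got {n}")
    # row k holds the sign pattern given by the bits of k
    k = np.arange(2**n)[:, None]
    signs = ((k >> np.arange(n)) & 1) * 2 - 1
    return (signs * diffs).mean(axis=1)


def p_value(observed: float, null: np.ndarray | Sequence[float]) -> float:
    """Two-sided proportion of |null| >= |observed| (ties are exceedances)."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution must be non-empty")
    return float(np.mean(np.abs(null) >= abs(observed) - _TIE_EPS))


def null_summary(
    null: np.ndarray | Sequence[float],
) -> tuple[float, float, tuple[float, float]]:
    """Mean, sample SD and empirical (2.5th, 97.5th) percentiles of the null.

    Percentiles use numpy's linear-interpolation convention.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution must be non-empty")
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    lo, hi = np.percentile(null, [2.5, 97.5])
    return float(null.mean()), sd, (float(lo), float(hi))


def effect_size(
    observed: float,
    null_sd: float | None = None,
    pairs: Sequence[PairedTrial] | None = None,
    kind: str = "null_sd",
) -> float:
    """Cohen's-d-style standardised effect.

    ``kind="null_sd"`` (default) divides the observed statistic by the SD of
    the resampled null; ``kind="classical"`` is the classical paired d,
    mean(differences) / sd(differences).
    """
    if kind == "null_sd":
        if null_sd is None:
            raise ValueError("null_sd is required for kind='null_sd'")
        if observed == 0:
            return 0.0
        if null_sd <= 0:
            raise ValueError("degenerate null: null_sd must be > 0")
        return float(observed / null_sd)
    if kind == "classical":
        if pairs is None:
            raise ValueError("pairs are required for kind='classical'")
        diffs = _as_diff_array(pairs)
        if np.all(diffs == diffs[0]) and diffs[0] == 0:
            return 0.0
        sd = diffs.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate sample: paired differences have zero SD")
        return float(diffs.mean() / sd)
    raise ValueError(f"unknown effect size kind {kind!r}")


def median_reduction(pairs: Sequence[PairedTrial]) -> float:
    """Percent reduction of the median landing count relative to control."""
    t = np.array([p.treatment_count for p in pairs], dtype=float)
    c = np.array([p.control_count for p in pairs], dtype=float)
    med_c = float(np.median(c))
    if med_c <= 0:
        raise ValueError("median control count is zero; percent reduction undefined")
    return float(100.0 * (med_c - np.median(t)) / med_c)


@dataclass
class DiagnosticsReport:
    """Advisory normality / variance-homogeneity diagnostics.

    Never gates the permutation test; degenerate inputs are flagged rather
    than raised.
    """

    shapiro_stat: float | None
    shapiro_p: float | None
    levene_stat: float | None
    levene_p: float | None
    notes: list[str] = field(default_factory=list)


def distribution_diagnostics(pairs: Sequence[PairedTrial]) -> DiagnosticsReport:
    """Shapiro-Wilk on paired differences; Levene across the two groups."""
    report = DiagnosticsReport(None, None, None, None)
    if len(pairs) < 3:
        report.notes.append("not computed: fewer than 3 pairs")
        return report
    diffs = _as_diff_array(pairs)
    t = np.array([p.treatment_count for p in pairs], dtype=float)
    c = np.array([p.control_count for p in pairs], dtype=float)
    if np.ptp(diffs) == 0:
        report.notes.append("degenerate input: paired differences are constant")
    else:
        sw = stats.shapiro(diffs)
        report.shapiro_stat, report.shapiro_p = float(sw.statistic), float(sw.pvalue)
    if np.ptp(t) == 0 and np.ptp(c) == 0:
        report.notes.append("degenerate input: zero spread in both groups")
    else:
        lv = stats.levene(t, c)
        report.levene_stat, report.levene_p = float(lv.statistic), float(lv.pvalue)
    return report


def paired_permutation_test(
    pairs: Sequence[PairedTrial],
    n_permutations: int = 10_000,
    scheme: str = "signflip",
    seed: int | None = None,
    effect_kind: str = "null_sd",
    exact: bool = False,
) -> PermutationResult:
    """Run the full paired permutation test and summarise the null.

    With ``exact=True`` (signflip only) the null is the exhaustive
    enumeration over all 2**n sign assignments instead of a Monte-Carlo
    sample; ``n_permutations`` is then ignored.
    """
    obs = observed_statistic(pairs)
    if exact:
        if scheme != "signflip":
            raise ValueError("exact enumeration is only defined for scheme='signflip'")
        null = exhaustive_signflip_null(pairs)
    else:
        null = permutation_null(pairs, n_permutations, scheme=scheme, seed=seed)
    mean, sd, interval = null_summary(null)
    p = p_value(obs, null)
    if effect_kind == "classical":
        d = effect_size(obs, pairs=pairs, kind="classical")
    else:
        d = effect_size(obs, null_sd=sd, kind="null_sd") if sd > 0 else float("nan")
    return PermutationResult(
        observed_difference=obs,
        p_value=p,
        null_mean=mean,
        null_sd=sd,
        null_interval=interval,
        effect_size=d,
        effect_size_kind=effect_kind,
        n_permutations=int(null.size),
        scheme=scheme,
        seed=seed,
        n_pairs=len(pairs),
        exact=exact,
    )


def pairs_from_frame(frame: pd.DataFrame) -> list[PairedTrial]:
    """Build trials from a ``trial_id,treatment_count,control_count`` frame."""
    required = {"trial_id", "treatment_count", "control_count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"paired-counts table is missing columns: {sorted(missing)}")
    return [
        PairedTrial(int(r.trial_id), int(r.treatment_count), int(r.control_count))
        for r in frame.itertuples(index=False)
    ]


def read_pairs_csv(path) -> list[PairedTrial]:
    """Read a paired-counts CSV (``trial_id,treatment_count,control_count``)."""
    return pairs_from_frame(pd.read_csv(path))
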