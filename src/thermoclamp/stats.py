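"""Paired and independent-sample tests and the paired-condition summary.

The paired t-test follows the textbook formula (t = mean(d) / (sd(d)/sqrt(n)),
sample sd, df = n-1, two-sided p). The Mann-Whitney U test is exact by full
enumeration of all C(n1+n2, n1) group labelings for small samples
(n1+n2 <= 16) and falls back to the tie-corrected normal approximation with
continuity correction for larger ones. Two-sided p values throughout.

:func:`compare_conditions` assembles the paired 23 degC vs 34 degC property
table (mean ± SEM per condition, paired t for within-cell properties,
Mann-Whitney for the per-command Kv time constants) with per-property n,
since cells can drop out of individual measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from scipy.stats import rankdata
from scipy.stats import t as _tdist

from .errors import DegenerateInputError, PairingError

__all__ = [
    "TestResult",
    "PropertyComparison",
    "ConditionComparison",
    "paired_t_test",
    "mann_whitney_u",
    "compare_conditions",
    "type_i_error_rate",
    "EXACT_ENUMERATION_MAX_N",
]

EXACT_ENUMERATION_MAX_N = 16


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    df: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p value outside [0, 1]")


def paired_t_test(x, y) -> TestResult:
    """Two-sided paired-samples t-test on index-aligned measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError("paired samples must be 1-D and equal length")
    n = len(x)
    if n < 2:
        raise PairingError("need at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("differences have zero variance")
    t = float(np.mean(d) / (sd / sqrt(n)))
    p = 2.0 * float(_tdist.sf(abs(t), n - 1))
    return TestResult(statistic=t, p_two_sided=min(p, 1.0), method="paired t", n=n, df=n - 1)


def _u_from_ranks(rank_sum_1: float, n1: int) -> float:
    return rank_sum_1 - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Exact by enumeration of all group labelings when n1 + n2 <= 16
    (two-sided p as the probability of a U at least as far from n1*n2/2 as
    observed; the enumeration distribution is symmetric about that center);
    otherwise the tie-corrected normal approximation with continuity
    correction. Reports U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise PairingError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks under ties
    u_obs = _u_from_ranks(float(ranks[:n1].sum()), n1)
    mu = n1 * n2 / 2.0
    n = n1 + n2

    if n <= EXACT_ENUMERATION_MAX_N:
        dev_obs = abs(u_obs - mu)
        hits = 0
        for idx in combinations(range(n), n1):
            u = _u_from_ranks(float(ranks[list(idx)].sum()), n1)
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        p = hits / comb(n, n1)
        method = "Mann-Whitney U (exact)"
    else:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var == 0.0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / sqrt(var)  # continuity-corrected
            p = 2.0 * float(_norm.sf(max(z, 0.0)))
        method = "Mann-Whitney U (normal approx)"
    return TestResult(
        statistic=float(u_obs), p_two_sided=min(p, 1.0), method=method, n1=n1, n2=n2
    )


# ---------------------------------------------------------------------------
# paired-condition comparison table
# ---------------------------------------------------------------------------

#: scalar per-cell properties compared with a paired t-test
PAIRED_PROPERTIES = (
    "r_hyperpolarized_mohm",
    "r_rest_mohm",
    "r_depolarized_mohm",
    "tau_ms",
    "rheobase_pa",
    "fmax_hz",
)


@dataclass(frozen=True)
class PropertyComparison:
    property: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    test: TestResult
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    command_mv: float | None = None


@dataclass(frozen=True)
class ConditionComparison:
    """Property table for condition A (e.g. 23 degC) vs B (e.g. 34 degC)."""

    label_a: str
    label_b: str
    rows: tuple

    def row(self, prop: str, command_mv: float | None = None) -> PropertyComparison:
        for r in self.rows:
            if r.property == prop and (
                command_mv is None or (r.command_mv is not None and abs(r.command_mv - command_mv) < 1e-6)
            ):
                return r
        raise KeyError(f"no row for {prop!r} (command {command_mv})")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "property": r.property,
                    "command_mv": r.command_mv,
                    f"mean_{self.label_a}": r.mean_a,
                    f"sem_{self.label_a}": r.sem_a,
                    f"mean_{self.label_b}": r.mean_b,
                    f"sem_{self.label_b}": r.sem_b,
                    "statistic": r.test.statistic,
                    "p_two_sided": r.test.p_two_sided,
                    "method": r.test.method,
                    "n": r.n if r.n is not None else f"{r.n1},{r.n2}",
                }
            )
        return pd.DataFrame(recs)


def _mean_sem(v: np.ndarray) -> tuple[float, float]:
    n = len(v)
    sem = float(np.std(v, ddof=1) / sqrt(n)) if n > 1 else float("nan")
    return float(np.mean(v)), sem


def compare_conditions(
    results_a: dict,
    results_b: dict,
    pairing: list | None = None,
    label_a: str = "23C",
    label_b: str = "34C",
) -> ConditionComparison:
    """Build the paired property table from per-cell measurement dicts.

    ``results_a``/``results_b`` map cell id -> property dict as produced by
    the cohort driver (scalar properties named as in
    :data:`PAIRED_PROPERTIES`, plus ``kv_tau_ms``: a command -> tau map).
    ``pairing`` lists the cell ids to pair; by default, every id present in
    both conditions. Ids named in an explicit pairing but missing from a
    condition raise :class:`PairingError`.
    """
    if pairing is None:
        pairing = sorted(set(results_a) & set(results_b))
    else:
        bad = [c for c in pairing if c not in results_a or c not in results_b]
        if bad:
            raise PairingError(f"cells missing from one condition: {bad}")
    if not pairing:
        raise PairingError("no paired cells")

    rows = []
    for prop in PAIRED_PROPERTIES:
        cells = [
            c
            for c in pairing
            if results_a[c].get(prop) is not None and results_b[c].get(prop) is not None
        ]
        if len(cells) < 2:
            continue
        va = np.array([results_a[c][prop] for c in cells], dtype=float)
        vb = np.array([results_b[c][prop] for c in cells], dtype=float)
        try:
            test = paired_t_test(va, vb)
        except DegenerateInputError:
            test = TestResult(
                statistic=0.0, p_two_sided=1.0, method="paired t (degenerate)",
                n=len(cells), df=len(cells) - 1,
            )
        (ma, sa), (mb, sb) = _mean_sem(va), _mean_sem(vb)
        rows.append(
            PropertyComparison(prop, ma, sa, mb, sb, test, n=len(cells))
        )

    # per-command Kv time constants: independent samples across conditions
    commands: set[float] = set()
    for res in list(results_a.values()) + list(results_b.values()):
        commands.update((res.get("kv_tau_ms") or {}).keys())
    for cmd in sorted(commands):
        va = np.array(
            [
                results_a[c]["kv_tau_ms"][cmd]
                for c in pairing
                if (results_a[c].get("kv_tau_ms") or {}).get(cmd) is not None
            ]
        )
        vb = np.array(
            [
                results_b[c]["kv_tau_ms"][cmd]
                for c in pairing
                if (results_b[c].get("kv_tau_ms") or {}).get(cmd) is not None
            ]
        )
        if len(va) < 1 or len(vb) < 1:
            continue
        test = mann_whitney_u(va, vb)
        (ma, sa), (mb, sb) = _mean_sem(va), _mean_sem(vb)
        rows.append(
            PropertyComparison(
                "kv_tau_ms", ma, sa, mb, sb, test, n1=len(va), n2=len(vb), command_mv=cmd
            )
        )
    return ConditionComparison(label_a=label_a, label_b=label_b, rows=tuple(rows))


def type_i_error_rate(
    n_pairs: int = 15,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    cell_sd: float = 1.0,
    noise_sd: float = 0.3,
) -> float:
    """Paired-t rejection rate under a true null (calibration check).

    Each replicate draws ``n_pairs`` cells from a common cell-level random
    effect and measures each twice with independent noise — the two
    conditions are statistically identical, so rejections at level alpha
    should occur in about alpha of replicates.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        base = rng.normal(0.0, cell_sd, n_pairs)
        x = base + rng.normal(0.0, noise_sd, n_pairs)
        y = base + rng.normal(0.0, noise_sd, n_pairs)
        if paired_t_test(x, y).p_two_sided < alpha:
            rejections += 1
    return rejections / reps
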