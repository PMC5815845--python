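"""Verbal n-back task: schedules, D-prime scoring, exclusions, residualization.

The task has two conditions.  In the 0-back condition the target is the
letter "x"; in the 2-back condition a stimulus is a target when it repeats
the letter shown two positions earlier.  Lure trials (the letter matches one
or three positions back without being a target) are planted at a configured
count to tempt false alarms.  Sensitivity is scored as
d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate) per condition, with the
0.5/N extreme-proportion correction so that perfect performance maps to a
finite ceiling.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ScheduleConstraintError, UndefinedScoreError

ZERO_BACK = "0-back"
TWO_BACK = "2-back"

#: Letters used as stimuli; "x" is reserved as the 0-back target.
_LETTERS = [c for c in string.ascii_lowercase if c != "x"]

#: Behavioral measures screened by the 4-SD outlier rule.
COGNITIVE_MEASURES = [
    "d_prime_2back",
    "d_prime_0back",
    "rt_difference",
    "episodic_memory",
    "item_familiarity",
]


@dataclass
class TaskSchedule:
    """Stimulus-level schedule: one row per stimulus.

    ``trials`` columns: block, condition, letter, is_target, is_lure.
    """

    trials: pd.DataFrame
    block_length: int = 14
    blocks_per_condition: int = 6
    targets_per_block: int = 3
    lure_count: int = 15

    def __len__(self) -> int:
        return len(self.trials)

    def condition_index(self, condition: str) -> np.ndarray:
        return (self.trials["condition"] == condition).to_numpy()


@dataclass
class ResponseLog:
    """Per-stimulus responses: 'target', 'nontarget' or 'missing'."""

    responses: pd.DataFrame  # columns: response, rt_ms

    def __len__(self) -> int:
        return len(self.responses)

    @property
    def response(self) -> np.ndarray:
        return self.responses["response"].to_numpy()


def _fill_two_back_block(rng, block_length, target_pos, lure_pos):
    """Construct one 2-back letter sequence with targets/lures exactly at the
    given positions; returns None when a choice dead-ends."""
    seq = [None] * block_length
    for i in range(block_length):
        back2 = seq[i - 2] if i >= 2 else None
        back1 = seq[i - 1] if i >= 1 else None
        back3 = seq[i - 3] if i >= 3 else None
        if i in target_pos:
            seq[i] = back2
        elif i in lure_pos:
            cands = [c for c in {back1, back3} if c is not None and c != back2]
            if not cands:
                return None
            seq[i] = cands[int(rng.integers(len(cands)))]
        else:
            forbidden = {back1, back2, back3}
            pool = [c for c in _LETTERS if c not in forbidden]
            seq[i] = pool[int(rng.integers(len(pool)))]
    return seq


def _block_counts(seq):
    n = len(seq)
    is_target = np.zeros(n, dtype=bool)
    is_lure = np.zeros(n, dtype=bool)
    for i in range(n):
        if i >= 2 and seq[i] == seq[i - 2]:
            is_target[i] = True
        elif (i >= 1 and seq[i] == seq[i - 1]) or (i >= 3 and seq[i] == seq[i - 3]):
            is_lure[i] = True
    return is_target, is_lure


def build_schedule(
    blocks_per_condition: int = 6,
    block_length: int = 14,
    targets_per_block: int = 3,
    lure_count: int = 15,
    seed: int = 0,
    max_retries: int = 2000,
) -> TaskSchedule:
    """Randomized schedule with exact target and lure counts.

    Defaults reproduce the study design: 6 blocks of 14 stimuli per
    condition, 3 targets per block, and 15 lures among the 84 2-back stimuli
    (a 17.9% lure fraction).
    """
    if targets_per_block >= block_length:
        raise ScheduleConstraintError("targets_per_block must be < block_length")
    rng = np.random.default_rng(seed)

    # Feasible lure slots per 2-back block: positions 1..L-1 minus targets.
    max_lures_per_block = block_length - 1 - targets_per_block
    if lure_count > max_lures_per_block * blocks_per_condition:
        raise ScheduleConstraintError(
            f"{lure_count} lures cannot fit into {blocks_per_condition} blocks"
        )
    base, extra = divmod(lure_count, blocks_per_condition)
    quotas = np.array([base + (i < extra) for i in range(blocks_per_condition)])
    rng.shuffle(quotas)

    two_back_blocks = []
    for quota in quotas:
        ok = None
        for _ in range(max_retries):
            target_pos = set(
                rng.choice(np.arange(2, block_length), size=targets_per_block, replace=False)
            )
            free = [i for i in range(1, block_length) if i not in target_pos]
            lure_pos = set(rng.choice(free, size=int(quota), replace=False))
            seq = _fill_two_back_block(rng, block_length, target_pos, lure_pos)
            if seq is None:
                continue
            is_t, is_l = _block_counts(seq)
            if is_t.sum() == targets_per_block and is_l.sum() == quota:
                ok = (seq, is_t, is_l)
                break
        if ok is None:
            raise ScheduleConstraintError("could not realize lure/target constraint")
        two_back_blocks.append(ok)

    zero_back_blocks = []
    for _ in range(blocks_per_condition):
        target_pos = set(rng.choice(block_length, size=targets_per_block, replace=False))
        seq = [
            "x" if i in target_pos else _LETTERS[int(rng.integers(len(_LETTERS)))]
            for i in range(block_length)
        ]
        is_t = np.array([c == "x" for c in seq])
        zero_back_blocks.append((seq, is_t, np.zeros(block_length, dtype=bool)))

    order = [ZERO_BACK] * blocks_per_condition + [TWO_BACK] * blocks_per_condition
    rng.shuffle(order)
    iters = {ZERO_BACK: iter(zero_back_blocks), TWO_BACK: iter(two_back_blocks)}
    rows = []
    for b, cond in enumerate(order):
        seq, is_t, is_l = next(iters[cond])
        for i in range(block_length):
            rows.append((b, cond, seq[i], bool(is_t[i]), bool(is_l[i])))
    trials = pd.DataFrame(rows, columns=["block", "condition", "letter", "is_target", "is_lure"])
    return TaskSchedule(
        trials=trials,
        block_length=block_length,
        blocks_per_condition=blocks_per_condition,
        targets_per_block=targets_per_block,
        lure_count=lure_count,
    )


def perfect_responses(schedule: TaskSchedule) -> ResponseLog:
    """Deterministic all-correct responder (no sampling, no missing trials)."""
    resp = np.where(schedule.trials["is_target"], "target", "nontarget")
    return ResponseLog(pd.DataFrame({"response": resp, "rt_ms": 500.0}))


def _corrected_rate(successes: int, n: int) -> float:
    # Extreme-proportion correction: 0 -> 0.5/N, 1 -> (N-0.5)/N.
    if successes == 0:
        return 0.5 / n
    if successes == n:
        return (n - 0.5) / n
    return successes / n


def score_dprime(responses: ResponseLog, schedule: TaskSchedule, condition: str) -> float:
    """Signal-detection sensitivity for one condition.

    Missing responses are dropped from both numerator and denominator.
    """
    if condition not in set(schedule.trials["condition"]):
        raise ValueError(f"condition {condition!r} not in schedule")
    sel = schedule.condition_index(condition)
    resp = responses.response[sel]
    is_target = schedule.trials["is_target"].to_numpy()[sel]
    usable = resp != "missing"
    n_t = int((usable & is_target).sum())
    n_nt = int((usable & ~is_target).sum())
    if n_t == 0 or n_nt == 0:
        raise UndefinedScoreError("no usable target or nontarget trials")
    hits = int(((resp == "target") & is_target & usable).sum())
    fas = int(((resp == "target") & ~is_target & usable).sum())
    H = _corrected_rate(hits, n_t)
    F = _corrected_rate(fas, n_nt)
    return float(stats.norm.ppf(H) - stats.norm.ppf(F))


def missing_fractions_by_block(log: ResponseLog, schedule: TaskSchedule) -> pd.DataFrame:
    """Per-block fractions of missing responses among targets / nontargets."""
    df = schedule.trials.copy()
    df["missing"] = log.response == "missing"
    rows = []
    for block, g in df.groupby("block"):
        t = g[g["is_target"]]
        nt = g[~g["is_target"]]
        rows.append(
            {
                "block": block,
                "target_missing_frac": t["missing"].mean() if len(t) else 0.0,
                "nontarget_missing_frac": nt["missing"].mean() if len(nt) else 0.0,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    table: pd.DataFrame,
    logs: list[ResponseLog] | None = None,
    schedule: TaskSchedule | None = None,
    measures: list[str] | None = None,
    missing_threshold: float = 0.30,
    block_count_threshold: int = 3,
    sd_threshold: float = 4.0,
) -> pd.DataFrame:
    """Flag subjects for exclusion; returns a copy with ``excluded`` and
    ``exclusion_reasons`` columns.

    Reasons: (a) missing responses in >30% of all stimuli; (b)/(c) >30% of
    target/nontarget stimuli missing in >= 3 blocks; (d) any cognitive measure
    beyond 4 SD of the pre-exclusion sample mean; (e) incomplete behavioral
    data.  The SD screen is computed once on the full sample, not iterated.
    """
    table = table.copy()
    if measures is None:
        measures = [m for m in COGNITIVE_MEASURES if m in table.columns]
    reasons: list[list[str]] = [[] for _ in range(len(table))]

    if logs is not None:
        if schedule is None:
            raise ValueError("schedule required when response logs are given")
        for i, log in enumerate(logs):
            miss = log.response == "missing"
            if miss.mean() > missing_threshold:
                reasons[i].append("a")
            per_block = missing_fractions_by_block(log, schedule)
            if (per_block["target_missing_frac"] > missing_threshold).sum() >= block_count_threshold:
                reasons[i].append("b")
            if (
                per_block["nontarget_missing_frac"] > missing_threshold
            ).sum() >= block_count_threshold:
                reasons[i].append("c")

    for m in measures:
        x = table[m].to_numpy(dtype=float)
        if np.isfinite(x).sum() < 2:
            continue
        mu, sd = np.nanmean(x), np.nanstd(x, ddof=1)
        if sd > 0:
            out = np.abs(x - mu) > sd_threshold * sd
            for i in np.flatnonzero(out & np.isfinite(x)):
                if "d" not in reasons[i]:
                    reasons[i].append("d")

    incomplete = table[measures].isna().any(axis=1).to_numpy() if measures else np.zeros(
        len(table), dtype=bool
    )
    for i in np.flatnonzero(incomplete):
        reasons[i].append("e")

    table["exclusion_reasons"] = [",".join(r) for r in reasons]
    table["excluded"] = [bool(r) for r in reasons]
    return table


def residualize(values: np.ndarray, factors: pd.DataFrame | None = None) -> np.ndarray:
    """OLS residuals of ``values`` on categorical factor indicators, scaled to
    mean 0, variance 1.

    With no factors this is an intercept-only model, i.e. plain z-scoring.
    Residuals that are numerically zero (the factors explain everything) are
    returned as zeros with a warning, since scaling is then degenerate.
    """
    values = np.asarray(values, dtype=float)
    if np.std(values) == 0:
        raise DegenerateInputError("constant values vector")
    X = _factor_design(factors, len(values))
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        import warnings

        warnings.warn("degenerate residual variance; returning zeros", stacklevel=2)
        return np.zeros_like(resid)
    return (resid - resid.mean()) / sd


def _factor_design(factors: pd.DataFrame | None, n: int) -> np.ndarray:
    if factors is None or factors.shape[1] == 0:
        return np.ones((n, 1))
    dummies = pd.get_dummies(factors.astype("category"), drop_first=True)
    return np.column_stack([np.ones(n), dummies.to_numpy(dtype=float)])


def residualize_matrix(
    X: np.ndarray, factors: pd.DataFrame | None, scale: bool = True
) -> np.ndarray:
    """Column-wise (per-voxel) batch residualization of a subjects x voxels
    matrix, optionally rescaled to unit variance per voxel ("standardized
    residuals")."""
    X = np.asarray(X, dtype=float)
    D = _factor_design(factors, X.shape[0])
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    R = X - D @ beta
    if scale:
        sd = R.std(axis=0, ddof=1)
        if np.any(sd < 1e-12):
            raise DegenerateInputError("zero-variance voxel after residualization")
        R = R / sd
    return R
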