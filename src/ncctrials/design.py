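"""Platform-trial structure: entry schedule, recruitment plan, periods,
calendar grid, and the analysis window for an evaluated arm.

Conventions
-----------
Time is the recruitment index: exactly one patient per time unit, so patient
``j`` is recruited at ``t = j`` (1-based).  Arm ``k`` (1-based; 0 is control)
opens after ``d_k`` patients have been recruited, i.e. it is eligible for
allocation from patient ``d_k + 1`` on, and it exits once it has accumulated
``n_arm`` patients.  A *period* is a maximal stretch of patients during which
the set of open arms is constant; any entry or exit starts a new period
(simultaneous events create a single boundary).  *Calendar intervals* cut the
same axis into fixed-length blocks of ``clength`` patients, independent of
design changes.

Exit times are computed from the deterministic equal-allocation flow: within
a period every open arm (control included) receives an equal share of
patients; the patient index at which an arm reaches ``n_arm`` is rounded up
to the next integer.  This convention is seed-independent and yields, e.g.,
a total of 1528 patients for ``K=4, d=250, n_arm=250``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "InfeasibleDesignError",
    "PlatformDesign",
    "PeriodRecord",
    "RecruitmentPlan",
    "PeriodMap",
    "CalendarGrid",
    "AnalysisWindow",
    "build_design",
    "plan_recruitment",
    "assign_periods",
    "assign_calendar",
    "analysis_window",
]

_EPS = 1e-9


class DesignError(ValueError):
    """Invalid design parameters."""


class InfeasibleDesignError(DesignError):
    """A structurally sound design that can never be recruited."""


@dataclass(frozen=True)
class PlatformDesign:
    """Structural parameters of a staggered-entry platform trial.

    Parameters
    ----------
    K : int
        Number of experimental arms (arm 0 is the shared control).
    n_arm : int
        Patients required per experimental arm.
    entry_schedule : tuple of int
        Cumulative recruitment counts ``d_1..d_K`` at which each arm opens;
        ``d_1 = 0`` and the schedule is nondecreasing.
    clength : int
        Calendar-interval length in patients.
    """

    K: int
    n_arm: int
    entry_schedule: tuple[int, ...]
    clength: int = 100

    def __post_init__(self) -> None:
        if self.K < 1:
            raise DesignError(f"K must be >= 1, got {self.K}")
        if self.n_arm < 1:
            raise DesignError(f"n_arm must be >= 1, got {self.n_arm}")
        if self.clength < 1:
            raise DesignError(f"clength must be >= 1, got {self.clength}")
        if len(self.entry_schedule) != self.K:
            raise DesignError(
                f"entry_schedule has {len(self.entry_schedule)} entries, expected K={self.K}"
            )
        if self.entry_schedule[0] != 0:
            raise DesignError(
                f"entry_schedule: d_1 must be 0, got {self.entry_schedule[0]}"
            )
        if any(b < a for a, b in zip(self.entry_schedule, self.entry_schedule[1:])):
            raise DesignError(
                f"entry_schedule must be nondecreasing, got {self.entry_schedule}"
            )

    @property
    def arms(self) -> tuple[int, ...]:
        """Experimental arm indices ``1..K``."""
        return tuple(range(1, self.K + 1))

    def block_size(self, n_active: int) -> int:
        """Permuted-block size for ``n_active`` open experimental arms."""
        return 2 * (n_active + 1)


def build_design(
    K: int,
    d_or_schedule: int | Sequence[int],
    n_arm: int,
    clength: int = 100,
) -> PlatformDesign:
    """Validate and construct a :class:`PlatformDesign`.

    ``d_or_schedule`` is either a scalar spacing ``d`` — expanded to the
    equidistant schedule ``d_k = d * (k - 1)`` — or an explicit schedule.
    """
    if np.isscalar(d_or_schedule):
        d = int(d_or_schedule)
        if d < 0:
            raise DesignError(f"entry spacing d must be >= 0, got {d}")
        schedule = tuple(d * (k - 1) for k in range(1, K + 1))
    else:
        schedule = tuple(int(x) for x in d_or_schedule)
    return PlatformDesign(K=K, n_arm=n_arm, entry_schedule=schedule, clength=clength)


@dataclass(frozen=True)
class PeriodRecord:
    """One period of the recruitment plan: patients ``start..end`` inclusive."""

    index: int
    start: int
    end: int
    active_arms: tuple[int, ...]  # experimental arms open in this period
    counts: dict[int, int]  # target patient counts per arm (0 = control)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RecruitmentPlan:
    """Deterministic recruitment plan derived from a :class:`PlatformDesign`."""

    design: PlatformDesign
    periods: tuple[PeriodRecord, ...]
    entry_time: dict[int, int]  # first patient index with positive allocation
    exit_time: dict[int, int]  # last patient index of the arm's active window
    N: int

    @property
    def boundaries(self) -> tuple[int, ...]:
        """Interior period boundaries (last patient index of each period but the final one)."""
        return tuple(p.end for p in self.periods[:-1])

    def period_of(self, t: int) -> int:
        """1-based period index containing recruitment time ``t``."""
        if not 1 <= t <= self.N:
            raise ValueError(f"t={t} outside trial 1..{self.N}")
        return int(np.searchsorted(np.asarray(self.boundaries), t, side="left")) + 1

    def to_frame(self) -> pd.DataFrame:
        """Plan as a table: period, start, end, active_arms, per-arm counts."""
        rows = []
        for p in self.periods:
            row: dict[str, object] = {
                "period": p.index,
                "start": p.start,
                "end": p.end,
                "active_arms": ";".join(str(a) for a in p.active_arms),
            }
            for arm in (0, *self.design.arms):
                row[f"n_arm{arm}"] = p.counts.get(arm, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def plan_recruitment(design: PlatformDesign) -> RecruitmentPlan:
    """Run the deterministic equal-allocation flow and lay out the periods.

    Within each period every open arm (including control) accrues patients at
    rate ``1 / (n_active + 1)``.  An arm exits at the first integer patient
    index by which it has reached ``n_arm``; entries and exits both start a
    new period, simultaneous events a single one.

    Raises
    ------
    InfeasibleDesignError
        If at some point no experimental arm is open while later arms are
        still waiting to enter (the arm can never accrue patients under the
        one-patient-per-time-unit model).
    """
    K, n_arm = design.K, design.n_arm
    sched = design.entry_schedule
    accrued = {k: 0.0 for k in design.arms}
    finished: set[int] = set()
    exit_time: dict[int, int] = {}
    # (boundary, accrual-deltas) trace, one segment per period
    segments: list[tuple[int, dict[int, float]]] = []
    t = 0.0

    while len(finished) < K:
        active = [
            k for k in design.arms if sched[k - 1] <= t + _EPS and k not in finished
        ]
        pending = [k for k in design.arms if sched[k - 1] > t + _EPS]
        if not active:
            k = pending[0]
            raise InfeasibleDesignError(
                f"arm {k} enters at d={sched[k - 1]} but recruitment has no open "
                f"experimental arm after patient {int(t)}; the design cannot be recruited"
            )
        share = 1.0 / (len(active) + 1)
        next_entry = min((sched[k - 1] for k in pending), default=math.inf)
        dt_exit = min((n_arm - accrued[k]) / share for k in active)
        t_exit = t + dt_exit
        if next_entry < t_exit - _EPS:
            t_next = float(next_entry)
        else:
            t_next = float(math.ceil(t_exit - _EPS))
        deltas = {k: share * (t_next - t) for k in active}
        for k in active:
            if accrued[k] + deltas[k] >= n_arm - _EPS:
                deltas[k] = n_arm - accrued[k]
                finished.add(k)
                exit_time[k] = int(round(t_next))
            accrued[k] += deltas[k]
        deltas[0] = (t_next - t) - sum(deltas.values())
        segments.append((int(round(t_next)), deltas))
        t = t_next

    N = int(round(t))
    entry_time = {k: sched[k - 1] + 1 for k in design.arms}

    # Merge consecutive segments with the same boundary is unnecessary: every
    # segment ends at an event.  Round per-arm counts by largest remainder so
    # each experimental arm totals exactly n_arm; control takes the slack.
    raw = np.zeros((len(segments), K + 1))
    for i, (_, deltas) in enumerate(segments):
        for k, v in deltas.items():
            raw[i, k] = v
    counts = np.floor(raw + _EPS).astype(int)
    for k in design.arms:
        short = n_arm - counts[:, k].sum()
        if short > 0:
            order = np.argsort(-(raw[:, k] - counts[:, k]))
            counts[order[:short], k] += 1
    starts = [1] + [b + 1 for b, _ in segments[:-1]]
    periods = []
    for i, ((end, deltas), start) in enumerate(zip(segments, starts)):
        active_arms = tuple(sorted(k for k in deltas if k != 0))
        length = end - start + 1
        c = {k: int(counts[i, k]) for k in active_arms}
        c[0] = length - sum(c.values())
        if c[0] < 0:
            raise AssertionError("control count rounding produced a negative value")
        periods.append(
            PeriodRecord(
                index=i + 1, start=start, end=end, active_arms=active_arms, counts=c
            )
        )
    return RecruitmentPlan(
        design=design,
        periods=tuple(periods),
        entry_time=entry_time,
        exit_time=exit_time,
        N=N,
    )


@dataclass(frozen=True)
class PeriodMap:
    """Mapping of recruitment times to period indices."""

    boundaries: tuple[int, ...]  # last patient index of each non-final period
    N: int

    @property
    def S(self) -> int:
        return len(self.boundaries) + 1

    def labels(self, t: np.ndarray | Sequence[int]) -> np.ndarray:
        """1-based period label for each recruitment time in ``t``."""
        t = np.asarray(t)
        if t.size and (t.min() < 1 or t.max() > self.N):
            raise ValueError("recruitment times outside 1..N")
        return np.searchsorted(np.asarray(self.boundaries), t, side="left") + 1


def assign_periods(plan: RecruitmentPlan) -> PeriodMap:
    """Period partition of ``1..N`` induced by the plan's entry/exit events."""
    return PeriodMap(boundaries=plan.boundaries, N=plan.N)


@dataclass(frozen=True)
class CalendarGrid:
    """Equidistant calendar partition of ``1..cutoff`` into ``clength``-patient units."""

    clength: int
    cutoff: int

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise DesignError(f"cutoff must be >= 1, got {self.cutoff}")
        if self.clength < 1:
            raise DesignError(f"clength must be >= 1, got {self.clength}")

    @property
    def C(self) -> int:
        return -(-self.cutoff // self.clength)

    def labels(self, t: np.ndarray | Sequence[int]) -> np.ndarray:
        """1-based calendar-interval label for each recruitment time in ``t``."""
        t = np.asarray(t)
        if t.size and (t.min() < 1 or t.max() > self.cutoff):
            raise ValueError("recruitment times outside 1..cutoff")
        return -(-t // self.clength)


def assign_calendar(cutoff: int, clength: int) -> CalendarGrid:
    """Calendar grid over patients ``1..cutoff``; interval ``c`` covers
    ``((c-1)*clength, c*clength]``, the last one truncated at ``cutoff``."""
    return CalendarGrid(clength=clength, cutoff=cutoff)


@dataclass(frozen=True)
class AnalysisWindow:
    """All data available when evaluating arm ``M``: patients with ``t <= t_exit``."""

    df: pd.DataFrame = field(repr=False)
    M: int
    t_entry: int
    t_exit: int
    K_M: tuple[int, ...]  # arms (incl. control) with data in the window
    S_M: int  # period containing t_exit
    C_M: int  # calendar interval containing t_exit
    clength: int

    @property
    def n(self) -> int:
        return len(self.df)


def analysis_window(data, plan: RecruitmentPlan, M: int) -> AnalysisWindow:
    """Slice the trial data at arm ``M``'s exit time.

    ``data`` is a :class:`~ncctrials.simulate.TrialData` or a DataFrame with
    columns ``t``, ``arm``, ``y`` (``period``/``calendar`` recomputed from the
    plan if absent).  Arms still recruiting at ``t_exit`` contribute their
    partial data.
    """
    df = getattr(data, "df", data)
    if M not in plan.exit_time:
        raise ValueError(f"arm {M} is not an experimental arm of this design (1..{plan.design.K})")
    t_exit = plan.exit_time[M]
    t_entry = plan.entry_time[M]
    sub = df[df["t"] <= t_exit].copy()
    if "period" not in sub.columns:
        sub["period"] = assign_periods(plan).labels(sub["t"].to_numpy())
    if "calendar" not in sub.columns:
        sub["calendar"] = assign_calendar(plan.N, plan.design.clength).labels(
            sub["t"].to_numpy()
        )
    if not (sub["arm"] == 0).any():
        raise ValueError(f"analysis window for arm {M} contains no control patients")
    if not (sub["arm"] == M).any():
        raise ValueError(f"analysis window contains no patients on arm {M}")
    K_M = tuple(sorted(sub["arm"].unique()))
    return AnalysisWindow(
        df=sub.reset_index(drop=True),
        M=M,
        t_entry=t_entry,
        t_exit=t_exit,
        K_M=K_M,
        S_M=plan.period_of(t_exit),
        C_M=assign_calendar(plan.N, plan.design.clength).labels([t_exit])[0],
        clength=plan.design.clength,
    )
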