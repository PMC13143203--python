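"""Behavioral and qPCR score formulas.

Three scores used to phenotype taste function and gene expression:

* **Two-bottle preference** — a 48 h free-choice assay with side-switched
  bottles; the score is the tastant volume as a percentage of total fluid
  consumed, with 50 the no-preference line.
* **Brief-access lick ratio** — randomized 5 s tastant presentations in a
  Davis-rig lickometer, blocks of five bottles (water plus four
  concentrations); the score per concentration is mean licks to tastant over
  mean licks to water, pooled over the two testing days. For the sweet panel
  the first block is excluded: the thirst-driven motivational state at
  session start drives maximal licking regardless of solution.
* **ΔΔCt fold change** — relative qPCR expression against a housekeeping
  gene (Rpl19 by default), centered on the control-group mean ΔCt and
  exponentiated base 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwoBottleRecord",
    "LickTrial",
    "LickSession",
    "CtTable",
    "two_bottle_preference",
    "lick_ratio",
    "thirst_metric",
    "ddct_fold_change",
    "SWEET_TASTANT",
]

#: tastant panel for which the first lickometer block is excluded by default
SWEET_TASTANT = "SC45647"

WATER = "water"


# ---------------------------------------------------------------------------
# two-bottle preference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoBottleRecord:
    """Consumption totals for one animal over the 48 h two-bottle test.

    Volumes are summed across the two 24 h halves (bottle sides switched at
    24 h to control for side preference).
    """

    tastant_volume_ml: float
    water_volume_ml: float
    tastant: str = SWEET_TASTANT
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.tastant_volume_ml < 0 or self.water_volume_ml < 0:
            raise ValueError("volumes must be non-negative")


def two_bottle_preference(record: TwoBottleRecord) -> float:
    """Preference score: tastant volume as a percentage of total intake.

    ``100 * tastant / (tastant + water)``; 50 means no preference. Undefined
    (error) when nothing was consumed.
    """
    total = record.tastant_volume_ml + record.water_volume_ml
    if total <= 0:
        raise ValueError("total consumption is zero; preference undefined")
    # clamp floating-point overshoot: the score is a percentage by definition
    return min(100.0, max(0.0, 100.0 * record.tastant_volume_ml / total))


# ---------------------------------------------------------------------------
# brief-access lickometer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LickTrial:
    """One 5 s bottle presentation: block index (1-based), bottle, licks."""

    block: int
    bottle: str
    licks: int

    def __post_init__(self) -> None:
        if self.block < 1:
            raise ValueError(f"block index must be >= 1, got {self.block}")
        if self.licks < 0 or int(self.licks) != self.licks:
            raise ValueError(f"licks must be a non-negative integer, got {self.licks}")


@dataclass(frozen=True)
class LickSession:
    """One day's lickometer session: up to eight blocks of five presentations
    (water and four concentrations of one tastant, in random order)."""

    trials: tuple[LickTrial, ...]
    day: int = 1
    tastant: str = SWEET_TASTANT

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))

    def licks_for(
        self, bottle: str, exclude_first_block: bool = False
    ) -> list[int]:
        return [
            t.licks
            for t in self.trials
            if t.bottle == bottle and not (exclude_first_block and t.block == 1)
        ]

    def first_block_total(self) -> int:
        """Total licks across the (five) first-block presentations."""
        first = [t.licks for t in self.trials if t.block == 1]
        if not first:
            raise ValueError(f"session day {self.day} has no first block")
        return int(sum(first))


def lick_ratio(
    session_pair: Sequence[LickSession],
    concentration: str,
    exclude_first_block: bool | None = None,
    per_day: bool = False,
) -> float:
    """Lick ratio for one tastant concentration over a pair of test days.

    Mean licks across eligible tastant trials at ``concentration`` divided by
    mean licks across eligible water trials, pooling trials over both days
    (set ``per_day=True`` to instead form one ratio per day and average —
    non-default).

    ``exclude_first_block`` defaults to automatic: the first block is dropped
    for the sweet tastant panel only.
    """
    sessions = list(session_pair)
    if not sessions:
        raise ValueError("need at least one session")
    if exclude_first_block is None:
        exclude_first_block = all(s.tastant == SWEET_TASTANT for s in sessions)

    def _ratio(sess: Iterable[LickSession]) -> float:
        tastant_licks: list[int] = []
        water_licks: list[int] = []
        for s in sess:
            tastant_licks += s.licks_for(concentration, exclude_first_block)
            water_licks += s.licks_for(WATER, exclude_first_block)
        if not tastant_licks or not water_licks:
            raise ValueError(
                f"no eligible trials for {concentration!r} and/or water"
            )
        water_mean = float(np.mean(water_licks))
        if water_mean == 0:
            raise ValueError("mean water licks is zero; ratio undefined")
        return float(np.mean(tastant_licks)) / water_mean

    if per_day:
        return float(np.mean([_ratio([s]) for s in sessions]))
    return _ratio(sessions)


def thirst_metric(session_pair: Sequence[LickSession]) -> float:
    """Motivational (thirst) index: first-block total licks averaged across
    the two testing days."""
    sessions = list(session_pair)
    if not sessions:
        raise ValueError("need at least one session")
    return float(np.mean([s.first_block_total() for s in sessions]))


# ---------------------------------------------------------------------------
# relative qPCR quantification
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Long-format qPCR Ct values: one row per (sample, gene).

    Columns ``sample_id``, ``group``, ``gene``, ``ct``. Every sample must
    carry a Ct for the housekeeping gene.
    """

    data: pd.DataFrame
    housekeeping: str = "Rpl19"

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.data["ct"].to_numpy(dtype=float))):
            raise ValueError("Ct values must be finite")
        hk = self.data[self.data["gene"] == self.housekeeping]
        samples = set(self.data["sample_id"])
        if set(hk["sample_id"]) != samples:
            missing_hk = sorted(samples - set(hk["sample_id"]))
            raise ValueError(
                f"samples missing housekeeping ({self.housekeeping}) Ct:"
                f" {missing_hk}"
            )


def ddct_fold_change(
    table: CtTable, target_gene: str, control_group: str = "control"
) -> pd.DataFrame:
    """Per-sample fold change of ``target_gene`` by the ΔΔCt method.

    ΔCt = Ct(target) − Ct(housekeeping) per sample; ΔΔCt = ΔCt − mean ΔCt of
    the control group (arithmetic mean); fold = 2^(−ΔΔCt). The geometric mean
    of the control samples' folds is 1 by construction.

    Returns a DataFrame with columns ``sample_id``, ``group``, ``delta_ct``,
    ``ddct``, ``fold``.
    """
    df = table.data
    target = df[df["gene"] == target_gene].set_index("sample_id")
    if target.empty:
        raise ValueError(f"no Ct rows for target gene {target_gene!r}")
    hk = df[df["gene"] == table.housekeeping].set_index("sample_id")["ct"]
    missing = set(target.index) - set(hk.index)
    if missing:
        raise ValueError(f"samples missing housekeeping Ct: {sorted(missing)}")

    delta_ct = target["ct"] - hk.loc[target.index]
    control = delta_ct[target["group"] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    ddct = delta_ct - control.mean()
    return pd.DataFrame(
        {
            "sample_id": target.index,
            "group": target["group"].to_numpy(),
            "delta_ct": delta_ct.to_numpy(),
            "ddct": ddct.to_numpy(),
            "fold": np.exp2(-ddct.to_numpy()),
        }
    )
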