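"""Relative fitness from serial-transfer competition assays.

Two strains are co-cultured and passaged daily by a 1:``dilution_factor``
transfer into fresh medium; at each sampled day the composition of the mix is
estimated by genotyping colonies. Under the model of the assay the culture
regrows to the same stationary density after every transfer, so the total
expansion per transfer equals the dilution factor and the realized doublings
of a strain whose population fraction moves from ``f_i`` to ``f_j`` over
``n`` transfers is::

    doublings = log2( f_j * D**n / f_i )

The relative fitness W is the ratio of the two strains' doublings over the
same interval (reference over test: W > 1 means the reference strain
out-doubled the test strain). Doublings are interval-additive and W obeys
W(A,B) * W(B,A) = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import ValidationError

__all__ = [
    "CompetitionSeries",
    "FitnessResult",
    "doublings",
    "relative_fitness",
]


@dataclass
class CompetitionSeries:
    """Strain-A population fractions over serial transfers.

    ``fractions`` holds columns ``time`` (integer days, T0 = 0),
    ``replicate`` and ``fraction_a`` in (0, 1). One transfer happens per day,
    so the number of transfers between two sampled times is their difference.
    """

    fractions: pd.DataFrame
    dilution_factor: float = 100.0
    strain_a: str = "test"
    strain_b: str = "reference"

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValidationError("dilution_factor must exceed 1")
        f = self.fractions["fraction_a"]
        if ((f <= 0) | (f >= 1)).any():
            raise ValidationError(
                "strain fractions must lie strictly in (0, 1): a strain at 0 "
                "or 1 has undefined doublings (extinct/fixed)"
            )

    @classmethod
    def from_counts(
        cls, counts: pd.DataFrame, dilution_factor: float = 100.0, **kw
    ) -> "CompetitionSeries":
        """Build from colony counts (columns time, replicate, strain_a_count,
        total); no pseudocounts are applied, so 0 or total positives fail."""
        df = counts.copy()
        df["fraction_a"] = df["strain_a_count"] / df["total"]
        return cls(
            fractions=df[["time", "replicate", "fraction_a"]],
            dilution_factor=dilution_factor,
            **kw,
        )

    @classmethod
    def from_fractions(
        cls,
        times: list[int],
        fractions_a: list[float],
        replicate: int = 1,
        dilution_factor: float = 100.0,
        **kw,
    ) -> "CompetitionSeries":
        return cls(
            fractions=pd.DataFrame(
                {"time": times, "replicate": replicate, "fraction_a": fractions_a}
            ),
            dilution_factor=dilution_factor,
            **kw,
        )


@dataclass
class FitnessResult:
    interval: tuple[int, int]
    per_replicate: pd.DataFrame  # replicate, doublings_a, doublings_b, w
    mean_w: float
    sd_w: float
    flagged: bool = False
    flags: list[str] = field(default_factory=list)


def doublings(
    f_initial: float,
    f_final: float,
    n_transfers: int,
    dilution_factor: float = 100.0,
) -> float:
    """Realized doublings of a strain across serial transfers.

    Assumes full regrowth between transfers (expansion factor = dilution
    factor per transfer).
    """
    for f in (f_initial, f_final):
        if not (0 < f < 1):
            raise ValidationError(
                f"fraction {f} outside (0, 1): doublings undefined"
            )
    if n_transfers < 1:
        raise ValidationError("n_transfers must be >= 1")
    if dilution_factor <= 0:
        raise ValidationError("dilution_factor must be positive")
    return math.log2(f_final * dilution_factor**n_transfers / f_initial)


def relative_fitness(
    series: CompetitionSeries,
    interval: tuple[int, int],
    reference: str = "B",
) -> FitnessResult:
    """Relative fitness W over an interval, per replicate and summarised.

    With ``reference="B"`` (default), W = doublings(B) / doublings(A) —
    matching the convention in which the unmodified reference strain is the
    numerator, so W > 1 reports a fitness cost of the modification carried by
    strain A. Replicates lacking either endpoint are skipped; degenerate
    (non-positive) doublings flag the result instead of raising.
    """
    t_i, t_j = interval
    if t_j <= t_i:
        raise ValidationError("interval must be increasing")
    n_transfers = t_j - t_i
    rows, flags = [], []
    df = series.fractions
    for rep, grp in df.groupby("replicate"):
        by_time = dict(zip(grp["time"], grp["fraction_a"]))
        if t_i not in by_time or t_j not in by_time:
            continue
        fa_i, fa_j = by_time[t_i], by_time[t_j]
        d_a = doublings(fa_i, fa_j, n_transfers, series.dilution_factor)
        d_b = doublings(1 - fa_i, 1 - fa_j, n_transfers, series.dilution_factor)
        if d_a <= 0 or d_b <= 0:
            flags.append(
                f"replicate {rep}: non-positive doublings (A={d_a:.3f}, "
                f"B={d_b:.3f})"
            )
            w = float("nan")
        else:
            w = d_b / d_a if reference == "B" else d_a / d_b
        rows.append(
            {"replicate": rep, "doublings_a": d_a, "doublings_b": d_b, "w": w}
        )
    if not rows:
        raise ValidationError(
            f"no replicate has both endpoints T{t_i} and T{t_j}"
        )
    per_rep = pd.DataFrame(rows)
    w = per_rep["w"].dropna()
    mean_w = float(w.mean()) if len(w) else float("nan")
    sd_w = float(w.std(ddof=1)) if len(w) > 1 else float("nan")
    return FitnessResult(
        interval=(t_i, t_j),
        per_replicate=per_rep,
        mean_w=mean_w,
        sd_w=sd_w,
        flagged=bool(flags),
        flags=flags,
    )
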