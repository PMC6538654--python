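"""Minichromosome establishment and loss-rate statistics.

The centromere establishment assay plates transformants carrying a
candidate minichromosome on low-adenine indicator plates: colonies that
retain the minichromosome stay white/pale pink, colonies that lose it
turn red. The establishment frequency is the percentage of transformant
colonies scoring white, corrected for occasional integration events
(pure-white on re-streaking) estimated from a checked subsample:

    establishment % = 100 * n_white * (1 - n_integrants/n_checked) / n_transformants

The half-sector stability assay estimates the per-division loss rate of
an established minichromosome: colonies that are >= 50% red lost the
minichromosome at the first division after plating, so

    loss rate per division % = 100 * n_half_sectored / n_non_pure_red_colonies

Percentages are reported rounded half-up to one decimal place.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EstablishmentCounts",
    "SectorCounts",
    "establishment_frequency",
    "loss_rate_per_division",
    "pooled_loss_rate",
    "reconstruct_count",
    "assay_table",
    "reference_assays",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed assay tables)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class EstablishmentCounts:
    """Replica-plating counts for the establishment assay."""

    n_transformants: int
    n_white: int
    n_white_checked: int = 0
    n_integrants_detected: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_white <= self.n_transformants):
            raise ValueError("require 0 <= n_white <= n_transformants")
        if self.n_white_checked:
            if not (0 <= self.n_integrants_detected <= self.n_white_checked <= self.n_white):
                raise ValueError(
                    "require n_integrants_detected <= n_white_checked <= n_white"
                )
        elif self.n_integrants_detected:
            raise ValueError("integrants reported without a checked sample")


@dataclass(frozen=True)
class SectorCounts:
    """Half-sector assay counts (pure-red colonies already excluded)."""

    n_colonies_total: int
    n_half_sectored: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_half_sectored <= self.n_colonies_total):
            raise ValueError("require 0 <= n_half_sectored <= n_colonies_total")


def establishment_frequency(c: EstablishmentCounts) -> float:
    """Establishment frequency in percent (one decimal, integration-adjusted)."""
    if c.n_transformants <= 0:
        raise ValueError("n_transformants must be > 0")
    if c.n_white_checked > 0:
        adjusted = c.n_white * (1.0 - c.n_integrants_detected / c.n_white_checked)
    else:
        adjusted = float(c.n_white)
    return round_half_up(100.0 * adjusted / c.n_transformants, 1)


def loss_rate_per_division(c: SectorCounts) -> float:
    """Per-division minichromosome loss rate in percent (one decimal)."""
    if c.n_colonies_total <= 0:
        raise ValueError("n_colonies_total must be > 0")
    return round_half_up(100.0 * c.n_half_sectored / c.n_colonies_total, 1)


def pooled_loss_rate(counts: list[SectorCounts]) -> float:
    """Count-weighted pooled loss rate across transformants, in percent."""
    total = sum(c.n_colonies_total for c in counts)
    sectored = sum(c.n_half_sectored for c in counts)
    if total <= 0:
        raise ValueError("no colonies")
    return round_half_up(100.0 * sectored / total, 1)


def reconstruct_count(rate_percent: float, n: int) -> int:
    """Integer event count consistent with a printed percentage and total."""
    return int(round_half_up(rate_percent / 100.0 * n, 0))


def assay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Compute assay statistics for a counts table.

    Expects columns ``plasmid, n_transformants, n_white, n_checked,
    n_integrants, n_colonies, n_half_sectored`` (the last two may be NA
    for minichromosomes that never established). Returns the table with
    ``establishment_pct`` and ``loss_pct`` columns appended.
    """
    out = df.copy()
    est, loss = [], []
    for _, row in df.iterrows():
        est.append(
            establishment_frequency(
                EstablishmentCounts(
                    int(row["n_transformants"]),
                    int(row["n_white"]),
                    int(row.get("n_checked", 0) or 0),
                    int(row.get("n_integrants", 0) or 0),
                )
            )
        )
        if pd.notna(row.get("n_colonies")) and int(row["n_colonies"]) > 0:
            loss.append(
                loss_rate_per_division(
                    SectorCounts(int(row["n_colonies"]), int(row["n_half_sectored"]))
                )
            )
        else:
            loss.append(float("nan"))
    out["establishment_pct"] = est
    out["loss_pct"] = loss
    return out


# Published establishment/loss measurements for chimeric minichromosomes
# carrying fission-yeast central-core fragments, used as reference inputs:
# establishment % (n transformants) and loss rate per division % (n colonies).
_REFERENCE_TSV = """\
plasmid	establishment_pct	n_transformants	loss_pct	n_colonies
pK-Sp-cnt2-8.5kb	94.0	217	5.8	3284
pK-So-cnt2-10kb	36.4	88	11.2	1636
pK-So-cnt3-6.5kb	40.1	262	5.8	3705
pK-So-cnt2-6.5kb	28.1	208	6.6	3621
pK-So-cnt2-4.7kb	5.2	973	6.8	7176
pK-So-cnt1-3.2kb	1.9	1529	11.5	2017
pK-So-cnt3-2.6kb	0.3	1443	21.1	1237
pKp-So-cnt3-6.5kb	6.6	916	15.9	2099
pKp-So-cnt3-3.6kb	0.0	1538
pKp	0.0	295
"""


def reference_assays() -> pd.DataFrame:
    """The published reference table of minichromosome assay rates."""
    return pd.read_csv(io.StringIO(_REFERENCE_TSV), sep="\t")
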