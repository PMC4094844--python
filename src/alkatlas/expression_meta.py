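"""Fold-change meta-analysis and reporter-activity arithmetic.

Works on log2 fold-change matrices of the kind exported from microarray
compendia (genes x conditions, missing cells allowed): per-gene extreme
changes, sign concordance between two genes, and relative promoter
activities from luciferase reporter counts with background subtraction.

A packaged fixture (``load_novobiocin_table``) holds the published log2
fold changes of *ado* and *aar* after novobiocin treatment combined with
heat, low temperature and salt stress.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd


def load_fold_change_csv(path) -> pd.DataFrame:
    """Genes x conditions matrix; first column = gene id, header = conditions."""
    df = pd.read_csv(path, index_col=0)
    return df


def load_novobiocin_table() -> pd.DataFrame:
    """The packaged novobiocin-stress log2 fold-change table for ado/aar."""
    with resources.files("alkatlas.data").joinpath("novobiocin_log2fc.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)


def top_change(table: pd.DataFrame, gene: str, direction: str = "max") -> tuple[str, float]:
    """The extreme log2 fold change of one gene and its condition.

    ``direction`` is ``max`` or ``min``; ties resolve to the first condition
    in column order. Raises ``KeyError``/``ValueError`` for an absent gene or
    an all-missing row.
    """
    if gene not in table.index:
        raise KeyError(f"gene {gene!r} not in table")
    row = table.loc[gene]
    if row.isna().all():
        raise ValueError(f"gene {gene!r} has no non-missing values")
    if direction == "max":
        cond = row.idxmax()
    elif direction == "min":
        cond = row.idxmin()
    else:
        raise ValueError("direction must be 'max' or 'min'")
    return str(cond), float(row[cond])


def sign_concordance(table: pd.DataFrame, gene_a: str, gene_b: str
                     ) -> tuple[float, list[str]]:
    """Fraction of shared conditions where two genes change in the same
    direction (zero counts as positive), plus the discordant condition list.

    Missing cells are excluded pairwise. Raises when the genes share no
    conditions with values.
    """
    for g in (gene_a, gene_b):
        if g not in table.index:
            raise KeyError(f"gene {g!r} not in table")
    a, b = table.loc[gene_a], table.loc[gene_b]
    mask = a.notna() & b.notna()
    if not mask.any():
        raise ValueError("no shared non-missing conditions")
    sa = np.where(a[mask] >= 0, 1, -1)
    sb = np.where(b[mask] >= 0, 1, -1)
    agree = sa == sb
    discordant = [str(c) for c, ok in zip(table.columns[mask], agree) if not ok]
    return float(agree.mean()), discordant


@dataclass(frozen=True)
class ReporterMeasurement:
    """Replicate luciferase light counts for one promoter-reporter fusion."""

    construct_id: str
    counts_per_s: tuple[float, ...]
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if not self.counts_per_s:
            raise ValueError("need at least one replicate")
        if any(c <= 0 for c in self.counts_per_s):
            raise ValueError("counts must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts_per_s))


@dataclass(frozen=True)
class PromoterActivity:
    construct_id: str
    activity: float          # fraction of the reference, background-subtracted
    background_flag: bool    # True when at or below the negative control


def relative_promoter_activity(
    measurements: Sequence[ReporterMeasurement],
    reference_id: str,
    negative_control_id: str,
) -> dict[str, PromoterActivity]:
    """Background-subtracted activity relative to a reference promoter.

    activity = (mean(construct) - mean(control)) / (mean(reference) - mean(control));
    constructs at or below the control are clamped to 0 and flagged as close
    to background. The control mean must be below the reference mean.
    """
    by_id = {m.construct_id: m for m in measurements}
    try:
        ref = by_id[reference_id]
        ctrl = by_id[negative_control_id]
    except KeyError as exc:
        raise KeyError(f"measurement {exc.args[0]!r} missing") from None
    denom = ref.mean - ctrl.mean
    if denom <= 0:
        raise ValueError("negative control mean must be below the reference mean")
    out = {}
    for m in measurements:
        raw = (m.mean - ctrl.mean) / denom
        out[m.construct_id] = PromoterActivity(
            m.construct_id, max(0.0, raw), background_flag=raw <= 0.0
        )
    return out
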