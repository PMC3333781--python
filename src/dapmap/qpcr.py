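"""qPCR enrichment arithmetic and the pre-hybridization decision rule.

Enrichment of a locus in the affinity-purified fraction is quantified as
fold = 2^dCt with dCt = mean Ct(input) - mean Ct(enriched); a target must be
enriched while a non-specific control locus is not before the sample is
worth labelling and hybridizing. Also holds the reporter-assay arithmetic
(relative fluorescence units = fluorescence / cell growth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "fold_enrichment",
    "enrichment_decision",
    "rfu",
    "read_ct_table",
    "DEFAULT_MIN_FOLD",
]

DEFAULT_MIN_FOLD = 2.0


@dataclass(frozen=True)
class QpcrMeasurement:
    target_id: str
    input_ct: tuple[float, ...]
    enriched_ct: tuple[float, ...]
    negative_control: bool = False

    def __post_init__(self) -> None:
        if not self.input_ct or not self.enriched_ct:
            raise ValueError(f"{self.target_id}: need at least one Ct replicate per fraction")
        if any(c <= 0 for c in self.input_ct + self.enriched_ct):
            raise ValueError(f"{self.target_id}: Ct values must be positive")


def fold_enrichment(m: QpcrMeasurement) -> tuple[float, float]:
    """(dCt, fold) with dCt = mean Ct(input) - mean Ct(enriched), fold = 2^dCt."""
    delta_ct = float(np.mean(m.input_ct) - np.mean(m.enriched_ct))
    return delta_ct, float(2.0**delta_ct)


def enrichment_decision(
    target_fold: float,
    negcontrol_fold: float,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> str:
    """proceed | repeat | flag_nonspecific.

    An enriched negative control signals non-specific pulldown and is flagged
    regardless of the target; an unenriched target means the binding/
    amplification steps should be repeated; otherwise proceed to labelling
    and hybridization.
    """
    if min_fold <= 0:
        raise ValueError("min_fold must be positive")
    if negcontrol_fold >= min_fold:
        return "flag_nonspecific"
    if target_fold < min_fold:
        return "repeat"
    return "proceed"


def rfu(fluorescence: float, od: float) -> float:
    """Relative fluorescence units: reporter fluorescence over cell growth (OD)."""
    if od <= 0:
        raise ValueError("OD must be positive")
    return fluorescence / od


def read_ct_table(path) -> list[QpcrMeasurement]:
    """Read tab-delimited Ct data with columns target, fraction, replicate, ct.

    fraction is 'input' or 'enriched'; an optional negative_control column
    (0/1) marks control loci.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"target", "fraction", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table missing columns {required - set(df.columns)}")
    out = []
    for target, grp in df.groupby("target", sort=True):
        neg = bool(grp["negative_control"].iloc[0]) if "negative_control" in grp else False
        out.append(
            QpcrMeasurement(
                target_id=str(target),
                input_ct=tuple(grp.loc[grp["fraction"] == "input", "ct"]),
                enriched_ct=tuple(grp.loc[grp["fraction"] == "enriched", "ct"]),
                negative_control=neg,
            )
        )
    return out
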