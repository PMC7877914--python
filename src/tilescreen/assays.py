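"""Relative-quantification qPCR: delta-delta-Ct and exon-skipping fraction.

Delta-Ct is the mean target Ct minus the mean reference-gene (e.g. actin)
Ct within a line; delta-delta-Ct subtracts the control line's delta-Ct
from the test line's; fold change is 2^(-ddCt) assuming perfect doubling
per cycle. For an exon-junction primer spanning a skipped exon, the
skipped fraction of transcripts is 1 - fold change (clamped to [0, 1]).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class QPCRMeasurement:
    """Triplicate Ct values for one primer pair in one line."""

    primer_pair: str
    line: str
    ct_replicates: tuple[float, ...]
    ref_ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        self.ct_replicates = _clean(self.ct_replicates, self)
        self.ref_ct_replicates = _clean(self.ref_ct_replicates, self)

    @property
    def delta_ct(self) -> float:
        """Mean target Ct minus mean reference Ct (cycles)."""
        return (float(np.mean(self.ct_replicates))
                - float(np.mean(self.ref_ct_replicates)))


def _clean(cts, meas) -> tuple[float, ...]:
    vals = tuple(float(c) for c in cts if c is not None and math.isfinite(c))
    if not vals:
        raise ValueError(f"{meas.primer_pair}/{meas.line}: all Ct "
                         "replicates missing")
    if any(v <= 0 for v in vals):
        raise ValueError("Ct values must be positive")
    if len(vals) < len(tuple(cts)):
        logger.warning("%s/%s: %d missing Ct replicate(s); using the rest",
                       meas.primer_pair, meas.line,
                       len(tuple(cts)) - len(vals))
    return vals


def delta_delta_ct(test: QPCRMeasurement,
                   control: QPCRMeasurement) -> dict:
    """ddCt = dCt(test) - dCt(control); fold change = 2^(-ddCt)."""
    ddct = test.delta_ct - control.delta_ct
    fc = 2.0 ** (-ddct)
    return {"primer_pair": test.primer_pair,
            "delta_ct_test": test.delta_ct,
            "delta_ct_control": control.delta_ct,
            "ddct": ddct, "fc": fc, "log2fc": -ddct}


def exon_skipping_fraction(fc_junction: float) -> float:
    """Fraction of transcripts missing the exon spanned by the primer."""
    if fc_junction < 0:
        raise ValueError("fold change cannot be negative")
    return min(max(1.0 - fc_junction, 0.0), 1.0)


def analyze_qpcr_table(table: pd.DataFrame, control_line: str,
                       junction_primers: list[str] | None = None
                       ) -> pd.DataFrame:
    """Per-primer ddCt analysis of a tidy Ct table.

    Input columns: line, primer_pair, ct1..ct3, ref_ct1..ref_ct3. Each
    test line's measurements are compared to ``control_line`` primer by
    primer; fc, log2fc and (for junction primers) the skipped fraction
    are reported.
    """
    def meas(row) -> QPCRMeasurement:
        return QPCRMeasurement(
            primer_pair=str(row["primer_pair"]), line=str(row["line"]),
            ct_replicates=(row["ct1"], row["ct2"], row["ct3"]),
            ref_ct_replicates=(row["ref_ct1"], row["ref_ct2"],
                               row["ref_ct3"]))

    controls = {str(r["primer_pair"]): meas(r)
                for _, r in table[table["line"] == control_line].iterrows()}
    rows = []
    for _, r in table[table["line"] != control_line].iterrows():
        m = meas(r)
        if m.primer_pair not in controls:
            raise ValueError(f"no control measurement for primer "
                             f"{m.primer_pair}")
        res = delta_delta_ct(m, controls[m.primer_pair])
        res["line"] = m.line
        if junction_primers and m.primer_pair in junction_primers:
            res["skipped_fraction"] = exon_skipping_fraction(res["fc"])
        rows.append(res)
    return pd.DataFrame(rows)
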