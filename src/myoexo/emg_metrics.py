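"""EMG normalization and scalar outcome measures.

Per subject and muscle, cycle ensembles are normalized to the maximum of
the Boots Only mean curve, so every downstream number is in fractions of
that reference.  The scalar outcome is the RMS of the normalized envelope
over the stance phase (swing for the tibialis anterior), compared across
conditions via percent change and standardized mean difference.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .signals import CYCLE_GRID, CycleEnsemble

#: Threshold below which a standardized mean difference is conventionally "small".
SMD_SMALL = 0.3

RMS_TABLE_COLUMNS = ("subject", "muscle", "condition", "phase", "rms")


def normalize_emg(
    ensembles: Mapping[str, CycleEnsemble], reference: str = "BootsOnly"
) -> dict[str, CycleEnsemble]:
    """Scale every condition's curves by the reference condition's mean-curve max.

    The reference maximum is taken from the mean curve rather than the
    single largest sample, so one spiking stride cannot deflate the whole
    subject.  Self-normalization leaves the reference mean curve with max 1.
    """
    if reference not in ensembles:
        raise KeyError(f"reference condition {reference!r} missing")
    ref_max = float(ensembles[reference].mean.max())
    if ref_max <= 0:
        raise ValueError("reference condition has zero maximum; cannot normalize")
    return {cond: ens.scaled(1.0 / ref_max) for cond, ens in ensembles.items()}


def phase_rms(ensemble: CycleEnsemble, phase: str = "stance", pooled: bool = False) -> float:
    """RMS of the ensemble over the stance or swing window.

    Per stride, the window is heel contact to that stride's toe-off
    (stance) or toe-off to 100% (swing); RMS is computed per stride and
    averaged across the ensemble (``pooled=True`` pools samples first).
    """
    if phase not in ("stance", "swing"):
        raise ValueError("phase must be 'stance' or 'swing'")
    vals = []
    for row, se in zip(ensemble.curves, ensemble.stance_end):
        mask = CYCLE_GRID <= se if phase == "stance" else CYCLE_GRID > se
        if not mask.any():
            raise ValueError(f"empty {phase} window (stance end {se}%)")
        vals.append(row[mask] ** 2)
    if pooled:
        return float(np.sqrt(np.mean(np.concatenate(vals))))
    return float(np.mean([np.sqrt(v.mean()) for v in vals]))


def percent_change(rms_a: float, rms_b: float) -> float:
    """Signed percent change from a to b: 100 * (b - a) / a."""
    if rms_a <= 0:
        raise ValueError("baseline RMS must be positive")
    return 100.0 * (rms_b - rms_a) / rms_a


def smd(mean_a: float, mean_b: float, sd_a: float, sd_b: float) -> float:
    """Standardized mean difference: |mean_a - mean_b| / mean of the SDs."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = 0.5 * (sd_a + sd_b)
    if denom == 0:
        raise ValueError("both SDs are zero; SMD undefined")
    return abs(mean_a - mean_b) / denom


def smd_label(value: float) -> str:
    """Conventional magnitude label (below 0.3 counts as small)."""
    return "small" if value < SMD_SMALL else "not small"


def rms_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Tidy per-(subject, muscle, condition) RMS table.

    One row per key triple; raises on duplicates or negative RMS so the
    stats stage can trust the table.
    """
    df = pd.DataFrame(list(rows), columns=list(RMS_TABLE_COLUMNS))
    if (df["rms"] < 0).any():
        raise ValueError("negative RMS in table")
    dup = df.duplicated(subset=["subject", "muscle", "condition"])
    if dup.any():
        raise ValueError("duplicate (subject, muscle, condition) rows")
    return df
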