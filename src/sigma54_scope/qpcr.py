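"""Efficiency-corrected relative expression from qPCR quantification cycles.

Implements the efficiency-corrected ddCq (Pfaffl) ratio

    ratio(s, t) = E_t^(Cq_t,cal - Cq_t,s) / E_ref^(Cq_ref,cal - Cq_ref,s)

with replicate-mean Cq values, a designated housekeeping reference target
(the gapC role) and a calibrator sample. E is the fold amplification per
cycle (2 = perfect doubling); when every E equals 2 the formula reduces to
the classic 2^(-ddCq). Efficiencies may be derived from standard-curve
slopes via E = 10^(-1/slope).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CqTable",
    "ExpressionRatio",
    "efficiency_from_slope",
    "relative_expression",
    "read_cq_table",
    "write_ratio_report",
]

E_WARN_RANGE = (1.5, 2.1)


def efficiency_from_slope(slope: float) -> float:
    """Per-cycle amplification E from a Cq-vs-log10(dilution) slope.

    E = 10^(-1/slope); a perfect doubling assay has slope -3.3219 (E = 2).
    Values outside [1.5, 2.1] are allowed but warned about.
    """
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    e = 10.0 ** (-1.0 / slope)
    if not E_WARN_RANGE[0] <= e <= E_WARN_RANGE[1]:
        warnings.warn(f"amplification efficiency E = {e:.3f} outside {E_WARN_RANGE}")
    return e


def _normalize_efficiency(e: float, target: str) -> float:
    if e > 3.0:  # given as percent (e.g. 95 for 95%): E = 1 + pct/100
        warnings.warn(
            f"efficiency {e} for {target} looks like a percentage; converting to {1 + e / 100:.3f}"
        )
        e = 1.0 + e / 100.0
    if not E_WARN_RANGE[0] <= e <= E_WARN_RANGE[1]:
        warnings.warn(f"efficiency {e:.3f} for {target} outside {E_WARN_RANGE}")
    return e


@dataclass
class CqTable:
    """Raw quantification cycles plus per-target efficiencies.

    ``data`` columns: sample, target, replicate, cq. ``efficiencies`` maps
    target id -> E in [1, 2]-ish fold-per-cycle units (percent inputs are
    auto-converted with a warning).
    """

    data: pd.DataFrame
    efficiencies: dict[str, float]
    reference_target: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "target", "replicate", "cq"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Cq table missing columns {sorted(missing)}")
        self.efficiencies = {
            t: _normalize_efficiency(float(e), t) for t, e in self.efficiencies.items()
        }
        targets = set(self.data["target"])
        if self.reference_target not in targets:
            raise ValueError(f"reference target {self.reference_target!r} absent from table")
        if self.calibrator_sample not in set(self.data["sample"]):
            raise ValueError(f"calibrator sample {self.calibrator_sample!r} absent from table")
        for t in targets:
            if t not in self.efficiencies:
                raise ValueError(f"no efficiency for target {t!r}")

    def mean_cq(self) -> pd.DataFrame:
        return (
            self.data.groupby(["sample", "target"])["cq"]
            .agg(["mean", "std", "min", "max", "count"])
            .reset_index()
        )


@dataclass(frozen=True)
class ExpressionRatio:
    """Fold change of one target in one sample relative to the calibrator."""

    sample_id: str
    target_id: str
    ratio: float
    log2_ratio: float
    ratio_low: float
    ratio_high: float
    n_replicates: int


def relative_expression(
    table: CqTable, pfaffl: bool = True
) -> list[ExpressionRatio]:
    """Efficiency-corrected ddCq ratios for every (sample, target).

    With ``pfaffl=False`` every efficiency is taken as 2 (plain 2^(-ddCq)).
    Replicate Cq values are averaged before the ratio; dispersion is
    propagated as a ratio interval from the replicate Cq ranges. Samples
    lacking reference measurements are skipped with a warning.
    """
    stats = table.mean_cq().set_index(["sample", "target"])
    samples = sorted(set(table.data["sample"]))
    targets = sorted(set(table.data["target"]))
    ref = table.reference_target
    cal = table.calibrator_sample
    out: list[ExpressionRatio] = []
    for s in samples:
        if (s, ref) not in stats.index or (cal, ref) not in stats.index:
            warnings.warn(f"sample {s!r} lacks reference-target measurements; skipped")
            continue
        ref_row_s = stats.loc[(s, ref)]
        ref_row_cal = stats.loc[(cal, ref)]
        e_ref = table.efficiencies[ref] if pfaffl else 2.0
        d_ref = float(ref_row_cal["mean"] - ref_row_s["mean"])
        for t in targets:
            if (s, t) not in stats.index or (cal, t) not in stats.index:
                continue
            row_s = stats.loc[(s, t)]
            row_cal = stats.loc[(cal, t)]
            e_t = table.efficiencies[t] if pfaffl else 2.0
            d_t = float(row_cal["mean"] - row_s["mean"])
            log2_ratio = d_t * math.log2(e_t) - d_ref * math.log2(e_ref)
            # worst-case interval from replicate half-ranges
            half_t = float(row_s["max"] - row_s["min"]) / 2.0
            half_r = float(ref_row_s["max"] - ref_row_s["min"]) / 2.0
            spread = abs(math.log2(e_t)) * half_t + abs(math.log2(e_ref)) * half_r
            out.append(
                ExpressionRatio(
                    sample_id=s,
                    target_id=t,
                    ratio=2.0 ** log2_ratio,
                    log2_ratio=log2_ratio,
                    ratio_low=2.0 ** (log2_ratio - spread),
                    ratio_high=2.0 ** (log2_ratio + spread),
                    n_replicates=int(row_s["count"]),
                )
            )
    return out


def read_cq_table(
    cq_path: str | Path,
    efficiency_path: str | Path,
    reference_target: str,
    calibrator_sample: str,
) -> CqTable:
    """Load Cq TSV (sample, target, replicate, cq) + efficiency TSV.

    The efficiency table carries either an ``efficiency`` column (E) or a
    ``slope`` column converted via E = 10^(-1/slope).
    """
    data = pd.read_csv(cq_path, sep="\t")
    eff = pd.read_csv(efficiency_path, sep="\t")
    if "efficiency" in eff.columns:
        effs = dict(zip(eff["target"], eff["efficiency"].astype(float)))
    elif "slope" in eff.columns:
        effs = {t: efficiency_from_slope(s) for t, s in zip(eff["target"], eff["slope"])}
    else:
        raise ValueError("efficiency table needs an 'efficiency' or 'slope' column")
    return CqTable(
        data=data,
        efficiencies=effs,
        reference_target=reference_target,
        calibrator_sample=calibrator_sample,
    )


def write_ratio_report(ratios: list[ExpressionRatio], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": [r.sample_id for r in ratios],
            "target": [r.target_id for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "log2_ratio": [r.log2_ratio for r in ratios],
            "ratio_low": [r.ratio_low for r in ratios],
            "ratio_high": [r.ratio_high for r in ratios],
            "n_replicates": [r.n_replicates for r in ratios],
        }
    ).to_csv(path, sep="\t", index=False)
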