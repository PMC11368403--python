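"""3C ligation-product quantification from qPCR Ct tables.

Each locus primer pair gets its own standard curve, fitted by least squares
to a dilution series of a calibration ligation (randomly re-ligated digested
genome): Ct = intercept + slope * log10(concentration), slope < 0, with
amplification efficiency 10^(-1/slope). Sample Ct values invert through the
curve to relative abundances on the calibration scale; interaction frequency
is the locus abundance divided by the bait-fragment abundance of the same
replicate (the bait restriction fragment is the internal control), averaged
over replicates. Inverting the per-locus curve generalizes the familiar
2^(-ddCt) shortcut, to which it reduces exactly when slope = -1/log10(2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps


@dataclass
class StandardCurve:
    locus_id: str
    intercept: float  # Ct at relative concentration 1
    slope: float      # cycles per log10(concentration); negative
    efficiency: float # amplification factor per cycle
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(
                f"locus {self.locus_id}: inverted dilution series (slope >= 0)"
            )


@dataclass
class CtTable:
    """qPCR observations: sample records plus per-locus calibration series.

    ``samples`` columns: locus_id, sample_id, replicate, ct.
    ``calibration`` columns: locus_id, relative_concentration, ct.
    """

    samples: pd.DataFrame
    calibration: pd.DataFrame
    bait_locus_id: str

    def __post_init__(self) -> None:
        for df, cols in ((self.samples, ["locus_id", "sample_id", "replicate", "ct"]),
                         (self.calibration, ["locus_id", "relative_concentration", "ct"])):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        if (self.samples["ct"] <= 0).any() or (self.calibration["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        have = set(self.samples["locus_id"])
        if self.bait_locus_id not in have:
            raise ValueError(f"bait locus {self.bait_locus_id} has no sample records")

    def calibration_for(self, locus_id: str) -> pd.DataFrame:
        return self.calibration[self.calibration["locus_id"] == locus_id]

    def to_tsv(self, samples_path: str | Path, calibration_path: str | Path) -> None:
        self.samples.to_csv(samples_path, sep="\t", index=False)
        self.calibration.to_csv(calibration_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, samples_path: str | Path, calibration_path: str | Path,
                 bait_locus_id: str) -> "CtTable":
        return cls(
            samples=pd.read_csv(samples_path, sep="\t"),
            calibration=pd.read_csv(calibration_path, sep="\t"),
            bait_locus_id=bait_locus_id,
        )


@dataclass
class InteractionProfile:
    """Mean and per-replicate interaction frequencies per (locus, sample)."""

    table: pd.DataFrame  # columns: locus_id, sample_id, replicate, if_value
    curves: dict[str, StandardCurve] = field(default_factory=dict)

    def mean_if(self) -> pd.DataFrame:
        return (
            self.table.groupby(["locus_id", "sample_id"], as_index=False)["if_value"]
            .agg(mean_if="mean", n="count")
        )


def fit_standard_curve(calibration: pd.DataFrame, locus_id: str | None = None) -> StandardCurve:
    """Least-squares fit of Ct on log10(relative concentration) for one locus."""
    if locus_id is None:
        ids = calibration["locus_id"].unique()
        if len(ids) != 1:
            raise ValueError("calibration records span multiple loci; pass locus_id")
        locus_id = str(ids[0])
        sub = calibration
    else:
        sub = calibration[calibration["locus_id"] == locus_id]
    conc = sub["relative_concentration"].to_numpy(dtype=float)
    ct = sub["ct"].to_numpy(dtype=float)
    if len(ct) < 3:
        raise ValueError(f"locus {locus_id}: need >= 3 calibration points")
    if (conc <= 0).any():
        raise ValueError(f"locus {locus_id}: non-positive concentration")
    x = np.log10(conc)
    if len(np.unique(x)) < 2:
        raise ValueError(f"locus {locus_id}: single dilution step")
    fit = _sps.linregress(x, ct)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope >= 0:
        raise ValueError(f"locus {locus_id}: inverted dilution series")
    return StandardCurve(
        locus_id=locus_id, intercept=intercept, slope=slope,
        efficiency=float(10 ** (-1 / slope)), r_squared=float(fit.rvalue ** 2),
    )


def quantify(ct: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Relative abundance on the calibration concentration scale."""
    out = 10 ** ((np.asarray(ct, dtype=float) - curve.intercept) / curve.slope)
    return float(out) if np.isscalar(ct) else out


def interaction_frequency(ct_table: CtTable) -> InteractionProfile:
    """Bait-normalized interaction frequency per locus, sample and replicate.

    IF(locus) = quantify(locus Ct) / quantify(bait Ct) within each
    (sample, replicate); replicates missing a bait record are dropped with a
    warning. The per-(locus, sample) summary is the arithmetic mean of the
    replicate IFs.
    """
    curves = {
        str(locus): fit_standard_curve(ct_table.calibration, str(locus))
        for locus in ct_table.calibration["locus_id"].unique()
    }
    bait = ct_table.bait_locus_id
    if bait not in curves:
        raise ValueError(f"bait locus {bait} has no calibration records")

    samples = ct_table.samples
    bait_ct = {
        (r.sample_id, r.replicate): r.ct
        for r in samples[samples["locus_id"] == bait].itertuples(index=False)
    }

    rows = []
    n_dropped = 0
    for r in samples[samples["locus_id"] != bait].itertuples(index=False):
        key = (r.sample_id, r.replicate)
        if key not in bait_ct:
            n_dropped += 1
            continue
        if r.locus_id not in curves:
            raise ValueError(f"locus {r.locus_id} has no calibration records")
        q_locus = quantify(r.ct, curves[r.locus_id])
        q_bait = quantify(bait_ct[key], curves[bait])
        rows.append({"locus_id": r.locus_id, "sample_id": r.sample_id,
                     "replicate": r.replicate, "if_value": q_locus / q_bait})
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} records lacking a bait Ct in the "
                      "same (sample, replicate)", stacklevel=2)
    if not rows:
        raise ValueError("no replicate has both locus and bait records")
    return InteractionProfile(table=pd.DataFrame(rows), curves=curves)
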