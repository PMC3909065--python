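"""RQ-PCR C_T processing: triplicate QC, inter-plate calibration,
amplification-efficiency QC and comparative-ΔCT relative quantification.

The quantification model is the classical comparative cycle-threshold
(ΔCT) method under an assumed amplification factor of 2: per miRNA *m*,

    RQ(s, m)  = 2^(maxCT(m) − CT(s, m))        (scaled to the lowest-
                                                expressing QC-passing sample,
                                                so min RQ = 1)
    NRQ(s, m) = RQ(s, m) / RQ(s, reference)    (normalised to miR-16)

Amplification efficiency enters only as an assay acceptance gate
(E within 100% ± 10%), never as a correction to the exponent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SD_THRESHOLD",
    "TriplicateSummary",
    "DilutionSeries",
    "EfficiencyResult",
    "ExpressionTable",
    "aggregate_triplicates",
    "calibrate_interplate",
    "compute_efficiency",
    "compute_expression",
]

#: Maximum acceptable standard deviation (cycles) for intra- and
#: inter-assay replicates.
SD_THRESHOLD = 0.28

#: Accepted amplification-efficiency window, percent.
EFFICIENCY_WINDOW = (90.0, 110.0)

DEFAULT_REFERENCE = "miR-16"


@dataclass(frozen=True)
class TriplicateSummary:
    """Replicate-aggregated C_T for one (sample, miRNA) with its QC verdict.

    ``qc_flag`` is one of ``pass`` (replicate SD ≤ 0.28), ``rescued_pair``
    (one outlier replicate dropped, remaining pair within threshold),
    ``fail_sd`` or ``fail_undetected``. ``n_used`` counts replicates behind
    ``mean_ct`` (0, 2 or 3).
    """

    sample_id: str
    mirna_id: str
    mean_ct: float  # NaN when QC failed
    sd_ct: float
    n_used: int
    qc_flag: str
    plate_id: str = ""

    @property
    def usable(self) -> bool:
        return self.qc_flag in ("pass", "rescued_pair")


@dataclass(frozen=True)
class DilutionSeries:
    """Points of a 10-fold dilution series: (log10 input, C_T)."""

    mirna_id: str
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("a dilution series needs at least 3 points")
        logs = [p[0] for p in self.points]
        diffs = np.diff(logs)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("log10 input must be strictly monotone")


@dataclass(frozen=True)
class EfficiencyResult:
    mirna_id: str
    slope: float
    efficiency_pct: float
    accepted: bool
    reason: str = ""


def _sd(values: Sequence[float]) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def aggregate_triplicates(ct_table: pd.DataFrame) -> list[TriplicateSummary]:
    """Collapse replicate wells to per-(sample, miRNA) means with QC flags.

    Replicates with the ``Undetermined`` token are excluded from the mean.
    If the numeric replicates' SD exceeds 0.28 cycles and dropping exactly
    one replicate brings the remaining pair within threshold, the pair is
    used and flagged ``rescued_pair`` (the drop minimising the pair SD);
    otherwise the well group fails QC. Fewer than two numeric replicates
    cannot demonstrate reproducibility and fail as undetected.
    """
    if ct_table.empty:
        raise ValueError("C_T table is empty")
    out: list[TriplicateSummary] = []
    grouped = ct_table.groupby(["sample_id", "mirna_id", "plate_id"], sort=True)
    for (sample, mirna, plate), grp in grouped:
        plate = str(plate)
        numeric = pd.to_numeric(grp["ct"], errors="coerce").dropna().to_numpy(dtype=float)
        if len(numeric) < 2:
            out.append(TriplicateSummary(sample, mirna, math.nan, math.nan, 0,
                                         "fail_undetected", plate))
            continue
        sd = _sd(numeric)
        if sd <= SD_THRESHOLD:
            out.append(TriplicateSummary(sample, mirna, float(numeric.mean()), sd,
                                         len(numeric), "pass", plate))
            continue
        if len(numeric) == 3:
            best_pair, best_sd = None, math.inf
            for drop in range(3):
                pair = np.delete(numeric, drop)
                psd = _sd(pair)
                if psd <= SD_THRESHOLD and psd < best_sd:
                    best_pair, best_sd = pair, psd
            if best_pair is not None:
                out.append(TriplicateSummary(sample, mirna, float(best_pair.mean()),
                                             best_sd, 2, "rescued_pair", plate))
                continue
        out.append(TriplicateSummary(sample, mirna, math.nan, sd, 0, "fail_sd", plate))
    return out


def calibrate_interplate(summaries: Iterable[TriplicateSummary],
                         iac_sample_id: str = "IAC") -> list[TriplicateSummary]:
    """Remove additive plate (run-to-run) offsets using the inter-assay control.

    Per plate, the offset is (mean IAC C_T on that plate − grand IAC mean),
    averaged over the QC-passing IAC miRNAs measured on the plate; it is
    subtracted from every mean C_T of that plate. With a single plate this is
    the identity. Plate effects are multiplicative on quantity, hence
    additive on the C_T scale.
    """
    summaries = list(summaries)
    plates = sorted({s.plate_id for s in summaries})
    if len(plates) <= 1:
        return summaries

    # IAC mean per (plate, miRNA) over usable wells only
    iac: dict[str, dict[str, float]] = {}
    for s in summaries:
        if s.sample_id == iac_sample_id and s.usable:
            iac.setdefault(s.plate_id, {})[s.mirna_id] = s.mean_ct
    missing = [p for p in plates if p not in iac or not iac[p]]
    if missing:
        raise ValueError(f"plates missing a usable inter-assay control: {missing}")

    # Use miRNAs present on all plates so offsets are comparable
    shared = set.intersection(*(set(iac[p]) for p in plates))
    if not shared:
        raise ValueError("no IAC miRNA passes QC on every plate")
    plate_mean = {p: float(np.mean([iac[p][m] for m in sorted(shared)])) for p in plates}
    grand = float(np.mean(list(plate_mean.values())))
    offset = {p: plate_mean[p] - grand for p in plates}

    out = []
    for s in summaries:
        if math.isnan(s.mean_ct):
            out.append(s)
        else:
            out.append(TriplicateSummary(s.sample_id, s.mirna_id,
                                         s.mean_ct - offset[s.plate_id], s.sd_ct,
                                         s.n_used, s.qc_flag, s.plate_id))
    return out


def compute_efficiency(series: DilutionSeries) -> EfficiencyResult:
    """Amplification efficiency from the semi-log standard-curve slope.

    Ordinary least squares of C_T on log10 input gives the slope (cycles per
    decade); E = (10^(−1/slope) − 1) × 100. A perfectly doubling assay has
    slope −log2(10) ≈ −3.3219 and E = 100%. Assays are accepted within
    100% ± 10%.
    """
    logs = np.array([p[0] for p in series.points], dtype=float)
    cts = np.array([p[1] for p in series.points], dtype=float)
    fit = stats.linregress(logs, cts)
    slope = float(fit.slope)
    if slope >= 0:
        return EfficiencyResult(series.mirna_id, slope, math.nan, False,
                                "non-negative slope: efficiency undefined")
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    lo, hi = EFFICIENCY_WINDOW
    accepted = lo <= eff <= hi
    return EfficiencyResult(series.mirna_id, slope, eff, accepted,
                            "" if accepted else f"efficiency outside {lo:.0f}-{hi:.0f}%")


class ExpressionTable:
    """Per-sample, per-miRNA normalised relative quantities (NRQ).

    Wraps a samples × miRNAs DataFrame of NRQ values (NaN where QC failed);
    the reference miRNA column is identically 1.
    """

    def __init__(self, nrq: pd.DataFrame, reference_mirna: str = DEFAULT_REFERENCE):
        if reference_mirna not in nrq.columns:
            raise ValueError(f"reference {reference_mirna!r} absent from table")
        self.nrq = nrq
        self.reference_mirna = reference_mirna

    @property
    def sample_ids(self) -> list[str]:
        return list(self.nrq.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.nrq.columns)

    def log10_nrq(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return np.log10(self.nrq)

    def to_csv(self, path) -> None:
        self.nrq.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path, reference_mirna: str = DEFAULT_REFERENCE) -> "ExpressionTable":
        return cls(pd.read_csv(path, index_col="sample_id"), reference_mirna)


def compute_expression(summaries: Iterable[TriplicateSummary],
                       reference_mirna: str = DEFAULT_REFERENCE,
                       exclude_samples: Sequence[str] = ("IAC",)) -> ExpressionTable:
    """Comparative-ΔCT quantification of QC-passing wells.

    Per miRNA, C_T values are scaled to the lowest-expressing (highest C_T)
    QC-passing sample — RQ = 2^(maxCT − CT), so min RQ = 1 — then normalised
    to the reference miRNA: NRQ = RQ_target / RQ_reference. Samples whose
    reference fails QC are dropped with a warning; cells failing QC are NaN.
    """
    rows: dict[str, dict[str, float]] = {}
    for s in summaries:
        if s.sample_id in exclude_samples or not s.usable:
            continue
        rows.setdefault(s.sample_id, {})[s.mirna_id] = s.mean_ct
    if not rows:
        raise ValueError("no QC-passing measurements")
    ct = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    ct = ct[sorted(ct.columns)]
    if reference_mirna not in ct.columns:
        raise ValueError(f"reference miRNA {reference_mirna!r} never passed QC")

    have_ref = ct[reference_mirna].notna()
    dropped = list(ct.index[~have_ref])
    if dropped:
        logger.warning("dropping %d sample(s) lacking a QC-passing reference: %s",
                       len(dropped), dropped)
    ct = ct.loc[have_ref]
    if ct.empty:
        raise ValueError("reference miRNA fails QC in every sample")

    max_ct = ct.max(axis=0)  # lowest-expressing sample per miRNA
    rq = np.power(2.0, max_ct - ct)
    nrq = rq.div(rq[reference_mirna], axis=0)
    return ExpressionTable(nrq, reference_mirna)


def summaries_to_frame(summaries: Iterable[TriplicateSummary]) -> pd.DataFrame:
    """Tidy view of triplicate summaries for CSV export."""
    return pd.DataFrame([{
        "sample_id": s.sample_id, "mirna_id": s.mirna_id, "plate_id": s.plate_id,
        "mean_ct": s.mean_ct, "sd_ct": s.sd_ct, "n_used": s.n_used, "qc_flag": s.qc_flag,
    } for s in summaries])
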