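"""Seeded synthetic cohorts with the statistical structure of a circulating
miRNA case/control study.

The generator emulates a TaqMan low-density-array style screen (one C_T per
sample and probe), a triplicate RQ-PCR validation cohort with plate effects
and an inter-assay control (IAC), paired tumour / tumour-associated-normal
(TAN) tissue, and 10-fold dilution series for amplification-efficiency QC.

Differential expression is planted on the C_T scale: a positive
``delta_ct_shift`` raises case C_T, i.e. lowers case expression, matching the
reduced circulating expression seen in Luminal A-like breast cancer. Every
draw flows from a single integer seed, so identical specs give byte-identical
tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "UNDETERMINED",
    "default_probe_ids",
    "generate_cohort",
    "generate_triplicate_plates",
    "generate_paired_tissue",
    "generate_dilution_series",
]

#: Token used for non-detected wells in C_T tables.
UNDETERMINED = "Undetermined"

CT_COLUMNS = ["sample_id", "mirna_id", "replicate", "plate_id", "ct"]
SAMPLE_COLUMNS = [
    "sample_id",
    "group",
    "age",
    "grade",
    "nodal_status",
    "stage",
    "invasive_size_mm",
    "whole_size_mm",
]

# Validation-cohort covariate distributions: ages are Normal(mean, sd) per
# group; categorical case covariates (with explicit missingness) follow the
# observed frequencies of a 44-case validation cohort.
CASE_AGE = (59.86, 13.45)
CONTROL_AGE = (44.21, 20.61)
AGE_BOUNDS = (18.0, 100.0)
GRADE_PROBS = {"1": 7 / 44, "2": 32 / 44, "3": 4 / 44, "missing": 1 / 44}
NODAL_PROBS = {"positive": 22 / 44, "negative": 19 / 44, "missing": 3 / 44}
STAGE_PROBS = {"1": 15 / 44, "2": 14 / 44, "3": 8 / 44, "4": 2 / 44, "missing": 3 / 44}
WHOLE_SIZE = (32.82, 26.30)
INVASIVE_SIZE = (27.41, 20.74)
WHOLE_SIZE_MISSING = 11 / 44
INVASIVE_SIZE_MISSING = 22 / 44


def default_probe_ids(n_probes: int) -> list[str]:
    """Synthetic probe universe: miR-p001 ... miR-pNNN."""
    width = max(3, len(str(n_probes)))
    return [f"miR-p{i:0{width}d}" for i in range(1, n_probes + 1)]


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a synthetic case/control cohort.

    All C_T-scale parameters are in cycles. ``delta_ct_shift`` > 0 means
    cases run later (lower expression). ``dropout_ct50`` is the true C_T at
    which the logistic detection probability is 0.5; wells also hard-censor
    at ``max_cycles``.
    """

    n_cases: int = 10
    n_controls: int = 10
    n_probes: int = 381
    planted_probe_ids: frozenset[str] = frozenset()
    delta_ct_shift: float = 2.0
    baseline_ct_mean: float = 28.0
    baseline_ct_sd: float = 3.0
    sample_offset_sd: float = 0.5
    biological_sd: float = 0.8
    replicate_sd: float = 0.12
    dropout_ct50: float = 36.0
    max_cycles: float = 40.0
    seed: int = 0
    probe_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("n_cases and n_controls must each be >= 2")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if min(self.replicate_sd, self.sample_offset_sd,
               self.baseline_ct_sd, self.biological_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        object.__setattr__(self, "planted_probe_ids", frozenset(self.planted_probe_ids))
        if self.probe_ids is not None:
            object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
            if len(self.probe_ids) != self.n_probes:
                raise ValueError("probe_ids length must equal n_probes")
        unknown = self.planted_probe_ids - set(self.universe)
        if unknown:
            raise ValueError(f"planted probes outside probe universe: {sorted(unknown)}")

    @property
    def universe(self) -> list[str]:
        return list(self.probe_ids) if self.probe_ids is not None else default_probe_ids(self.n_probes)


def _rng(spec_seed: int, *labels: str) -> np.random.Generator:
    """Named substream: reproducible and independent of evaluation order."""
    keys = [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(spec_seed) & 0x7FFFFFFF, *keys]))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float], size: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=size, p=p)


def _make_sample_sheet(spec: CohortSpec, rng: np.random.Generator,
                       case_ids: Sequence[str], control_ids: Sequence[str]) -> pd.DataFrame:
    """Covariates follow the validation cohort's distributions; controls carry
    no tumour covariates (grade/nodal/stage/sizes missing)."""
    n_cases, n_controls = len(case_ids), len(control_ids)
    case_age = _truncated_normal(rng, *CASE_AGE, *AGE_BOUNDS, n_cases)
    ctrl_age = _truncated_normal(rng, *CONTROL_AGE, *AGE_BOUNDS, n_controls)
    grade = _draw_categorical(rng, GRADE_PROBS, n_cases)
    nodal = _draw_categorical(rng, NODAL_PROBS, n_cases)
    stage = _draw_categorical(rng, STAGE_PROBS, n_cases)
    whole = _truncated_normal(rng, *WHOLE_SIZE, 1.0, 200.0, n_cases)
    inv = np.minimum(_truncated_normal(rng, *INVASIVE_SIZE, 1.0, 200.0, n_cases), whole)
    whole_miss = rng.random(n_cases) < WHOLE_SIZE_MISSING
    inv_miss = (rng.random(n_cases) < INVASIVE_SIZE_MISSING) | whole_miss

    rows = []
    for i, sid in enumerate(case_ids):
        rows.append({
            "sample_id": sid,
            "group": "case",
            "age": round(float(case_age[i]), 1),
            "grade": grade[i],
            "nodal_status": nodal[i],
            "stage": stage[i],
            "invasive_size_mm": np.nan if inv_miss[i] else round(float(inv[i]), 1),
            "whole_size_mm": np.nan if whole_miss[i] else round(float(whole[i]), 1),
        })
    for i, sid in enumerate(control_ids):
        rows.append({
            "sample_id": sid,
            "group": "control",
            "age": round(float(ctrl_age[i]), 1),
            "grade": "missing",
            "nodal_status": "missing",
            "stage": "missing",
            "invasive_size_mm": np.nan,
            "whole_size_mm": np.nan,
        })
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def _true_ct_matrix(spec: CohortSpec, rng: np.random.Generator,
                    groups: np.ndarray, probes: Sequence[str],
                    sample_offsets: np.ndarray,
                    stable_probes: frozenset[str] = frozenset()) -> np.ndarray:
    """True (pre-replicate) C_T per (sample, probe): probe baseline +
    per-sample technical offset + between-subject biological variation +
    planted case shift. ``stable_probes`` (e.g. the endogenous reference)
    carry no biological variation."""
    baselines = rng.normal(spec.baseline_ct_mean, spec.baseline_ct_sd, size=len(probes))
    planted = np.array([p in spec.planted_probe_ids for p in probes])
    stable = np.array([p in stable_probes for p in probes])
    ct = baselines[None, :] + sample_offsets[:, None]
    bio = rng.normal(0.0, spec.biological_sd, size=ct.shape)
    ct = ct + np.where(stable[None, :], 0.0, bio)
    ct = ct + np.where(planted[None, :] & (groups[:, None] == "case"), spec.delta_ct_shift, 0.0)
    return ct


def _apply_detection(rng: np.random.Generator, true_ct: np.ndarray,
                     dropout_ct50: float, max_cycles: float) -> np.ndarray:
    """Logistic non-detection (slope 1 per cycle) plus hard censoring."""
    p_detect = 1.0 / (1.0 + np.exp(true_ct - dropout_ct50))
    detected = rng.random(true_ct.shape) < p_detect
    return detected & (true_ct <= max_cycles)


def _ct_long_table(sample_ids: Sequence[str], probes: Sequence[str],
                   measured: np.ndarray, detected: np.ndarray,
                   replicate: np.ndarray | int, plate_id: np.ndarray | str) -> pd.DataFrame:
    n_s, n_p = measured.shape[:2]
    reps = np.broadcast_to(np.asarray(replicate), measured.shape)
    plates = np.broadcast_to(np.asarray(plate_id, dtype=object), measured.shape)
    ct = np.where(detected, np.round(measured, 4).astype(object), UNDETERMINED)
    if measured.ndim == 2:
        df = pd.DataFrame({
            "sample_id": np.repeat(sample_ids, n_p),
            "mirna_id": np.tile(probes, n_s),
            "replicate": reps.ravel(),
            "plate_id": plates.ravel(),
            "ct": ct.ravel(),
        })
    else:  # (samples, probes, replicates)
        n_r = measured.shape[2]
        df = pd.DataFrame({
            "sample_id": np.repeat(sample_ids, n_p * n_r),
            "mirna_id": np.tile(np.repeat(probes, n_r), n_s),
            "replicate": reps.ravel(),
            "plate_id": plates.ravel(),
            "ct": ct.ravel(),
        })
    return df[CT_COLUMNS]


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a single-replicate array-style screen.

    Returns ``(sample_sheet, ct_table)``. The C_T table has exactly one row
    per (sample, probe); wells failing the logistic detection draw or running
    past ``max_cycles`` carry the literal token ``"Undetermined"``.
    """
    probes = spec.universe
    case_ids = [f"case_{i:03d}" for i in range(1, spec.n_cases + 1)]
    ctrl_ids = [f"ctrl_{i:03d}" for i in range(1, spec.n_controls + 1)]
    sample_ids = case_ids + ctrl_ids
    groups = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)

    sheet = _make_sample_sheet(spec, _rng(spec.seed, "covariates"), case_ids, ctrl_ids)
    rng = _rng(spec.seed, "screen")
    offsets = rng.normal(0.0, spec.sample_offset_sd, size=len(sample_ids))
    true_ct = _true_ct_matrix(spec, rng, groups, probes, offsets)
    measured = true_ct + rng.normal(0.0, spec.replicate_sd, size=true_ct.shape)
    detected = _apply_detection(rng, true_ct, spec.dropout_ct50, spec.max_cycles)
    ct = _ct_long_table(sample_ids, probes, measured, detected, 1, "array")
    return sheet, ct


def generate_triplicate_plates(
    spec: CohortSpec,
    mirna_panel: Sequence[str],
    *,
    plate_sd: float = 0.15,
    samples_per_plate: int = 10,
    iac_sample_id: str = "IAC",
    reference_mirna: str = "miR-16",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a triplicate RQ-PCR validation run over ``mirna_panel``.

    Samples are distributed over plates of ``samples_per_plate``; each plate
    receives an additive Normal(0, plate_sd) run shift applied to all its
    wells, and carries the same inter-assay control sample (one shared truth
    across plates) so downstream calibration can remove the shifts.

    The panel must include the endogenous reference (default miR-16), which
    is never planted and so is stable between groups.
    """
    panel = list(dict.fromkeys(mirna_panel))
    if not panel:
        raise ValueError("mirna_panel must be non-empty")
    if reference_mirna not in panel:
        raise ValueError(f"panel must include the reference miRNA {reference_mirna!r}")
    if reference_mirna in spec.planted_probe_ids:
        raise ValueError("the reference miRNA cannot carry a planted effect")

    case_ids = [f"vcase_{i:03d}" for i in range(1, spec.n_cases + 1)]
    ctrl_ids = [f"vctrl_{i:03d}" for i in range(1, spec.n_controls + 1)]
    sheet = _make_sample_sheet(spec, _rng(spec.seed, "val-covariates"), case_ids, ctrl_ids)

    rng = _rng(spec.seed, "validation")
    sample_ids = case_ids + ctrl_ids
    groups = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)
    offsets = rng.normal(0.0, spec.sample_offset_sd, size=len(sample_ids))

    # miRNA-level spec: panel members keep their planted status.
    panel_spec = replace(spec, n_probes=len(panel), probe_ids=tuple(panel),
                         planted_probe_ids=spec.planted_probe_ids & set(panel))
    stable = frozenset({reference_mirna})
    true_ct = _true_ct_matrix(panel_spec, rng, groups, panel, offsets, stable)

    # IAC truth shared across plates: a pseudo-control with its own offset.
    iac_offset = rng.normal(0.0, spec.sample_offset_sd)
    iac_true = _true_ct_matrix(panel_spec, _rng(spec.seed, "validation", "iac-baseline"),
                               np.array(["control"]), panel, np.array([iac_offset]),
                               stable)[0]

    n_plates = int(np.ceil(len(sample_ids) / samples_per_plate))
    plate_names = [f"plate_{k + 1:02d}" for k in range(n_plates)]
    plate_shift = rng.normal(0.0, plate_sd, size=n_plates)
    plate_of_sample = np.repeat(np.arange(n_plates), samples_per_plate)[: len(sample_ids)]

    frames = []
    for k, plate in enumerate(plate_names):
        on_plate = np.where(plate_of_sample == k)[0]
        ids = [sample_ids[i] for i in on_plate] + [iac_sample_id]
        truth = np.vstack([true_ct[on_plate], iac_true[None, :]]) + plate_shift[k]
        trip = truth[:, :, None] + rng.normal(0.0, spec.replicate_sd, size=(len(ids), len(panel), 3))
        detected = _apply_detection(rng, np.repeat(truth[:, :, None], 3, axis=2),
                                    spec.dropout_ct50, spec.max_cycles)
        reps = np.broadcast_to(np.array([1, 2, 3]), trip.shape)
        frames.append(_ct_long_table(ids, panel, trip, detected, reps, plate))
    ct = pd.concat(frames, ignore_index=True)
    return sheet, ct


def generate_paired_tissue(
    spec: CohortSpec,
    *,
    n_pairs: int | None = None,
    pair_offset_sd: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired tumour / TAN tissue screen sharing a per-subject offset.

    Reuses the blood generator's model: the planted shift is applied to the
    tumour member of each pair, so a positive ``delta_ct_shift`` means lower
    expression in tumour than in tumour-associated normal tissue.
    """
    n = n_pairs if n_pairs is not None else spec.n_cases
    if n < 2:
        raise ValueError("need at least 2 tissue pairs")
    offset_sd = pair_offset_sd if pair_offset_sd is not None else spec.sample_offset_sd
    probes = spec.universe
    tumor_ids = [f"tumor_{i:03d}" for i in range(1, n + 1)]
    tan_ids = [f"tan_{i:03d}" for i in range(1, n + 1)]

    rng = _rng(spec.seed, "tissue")
    subject_offset = rng.normal(0.0, offset_sd, size=n)
    offsets = np.concatenate([subject_offset, subject_offset])  # shared within a pair
    groups = np.array(["case"] * n + ["control"] * n)  # tumor carries the shift
    true_ct = _true_ct_matrix(spec, rng, groups, probes, offsets)
    measured = true_ct + rng.normal(0.0, spec.replicate_sd, size=true_ct.shape)
    detected = _apply_detection(rng, true_ct, spec.dropout_ct50, spec.max_cycles)

    ids = tumor_ids + tan_ids
    ct = _ct_long_table(ids, probes, measured, detected, 1, "tissue_array")

    age = _truncated_normal(_rng(spec.seed, "tissue-covariates"), 54.27, 9.26, *AGE_BOUNDS, n)
    rows = []
    for grp, id_list in (("tumor_tissue", tumor_ids), ("tan_tissue", tan_ids)):
        for i, sid in enumerate(id_list):
            rows.append({
                "sample_id": sid, "group": grp, "age": round(float(age[i]), 1),
                "grade": "missing", "nodal_status": "missing", "stage": "missing",
                "invasive_size_mm": np.nan, "whole_size_mm": np.nan,
            })
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS), ct


def generate_dilution_series(
    true_efficiency_pct: float,
    n_points: int = 5,
    top_ct: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    mirna_id: str = "miR-16",
):
    """10-fold dilution series for amplification-efficiency QC.

    Point k (k = 0 .. n_points-1) has log10 input ``-k`` and
    ``C_T = top_ct + k * log(10) / log(1 + E/100) + noise``, so a perfectly
    doubling assay (E = 100%) spaces points log2(10) = 3.3219 cycles apart.
    """
    from .qpcr import DilutionSeries  # local import to avoid a cycle

    if not 50.0 <= true_efficiency_pct <= 150.0:
        raise ValueError("true_efficiency_pct must lie in [50, 150]")
    if n_points < 3:
        raise ValueError("need at least 3 dilution points")
    rng = np.random.default_rng(seed)
    k = np.arange(n_points, dtype=float)
    spacing = np.log(10.0) / np.log1p(true_efficiency_pct / 100.0)
    ct = top_ct + k * spacing + rng.normal(0.0, noise_sd, size=n_points)
    points = list(zip((-k).tolist(), ct.tolist()))
    return DilutionSeries(mirna_id=mirna_id, points=points)
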