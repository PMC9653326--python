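"""Patient-level correlation analysis and the "typical lesion".

Each patient's disconnection region profile is correlated (Pearson,
across atlas regions) with the group fMRI region profile. Patients
whose r exceeds a large-effect threshold (default r > 0.5, one-sided:
an anticorrelated lesion is not a pure lesion of the network) are
counted as "pure lesions" of the decoded network, and the single
patient with maximal r defines the typical lesion — the damage pattern
whose disconnection best mirrors the activation pattern.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disconnect import LesionMask
from .errors import DegenerateDataError, ParameterError
from .fmri_group import RegionProfile
from .io_nifti import save_volume

log = logging.getLogger(__name__)


@dataclass
class PatientCorrelation:
    """Pearson correlation of one patient's disconnection profile."""

    patient_id: str
    r: float
    r_squared: float
    n_regions: int
    valid: bool = True
    reason: str = ""


@dataclass
class TypicalLesionReport:
    """Cohort-level summary of patient-activation correlations."""

    correlations: list[PatientCorrelation]
    pure_fraction: float  # percent of valid patients with r > threshold
    effect_threshold: float
    top_patient: PatientCorrelation
    n_excluded: int
    typical_lesion_map: LesionMask | None = field(default=None, repr=False)


def patient_correlation(disc_profile: RegionProfile,
                        fmri_profile: RegionProfile,
                        patient_id: str = "") -> PatientCorrelation:
    """Pearson r across regions between one patient and the fMRI profile.

    A zero-variance disconnection profile (lesion touching no tract)
    yields an invalid result flagged with a reason instead of an error,
    so cohort analyses can exclude it with bookkeeping intact.
    """
    if not disc_profile.aligned_with(fmri_profile):
        raise ParameterError(
            "profiles are not aligned on identical region ids"
        )
    n = disc_profile.n_regions
    if n < 3:
        raise ParameterError(f"need >= 3 regions, got {n}")
    pid = patient_id or disc_profile.source_tag or "unknown"
    if fmri_profile.values.std() == 0:
        raise DegenerateDataError("fMRI profile has zero variance")
    if disc_profile.values.std() == 0:
        return PatientCorrelation(patient_id=pid, r=math.nan,
                                  r_squared=math.nan, n_regions=n,
                                  valid=False,
                                  reason="zero-variance disconnection "
                                         "profile")
    r = float(stats.pearsonr(disc_profile.values,
                             fmri_profile.values).statistic)
    return PatientCorrelation(patient_id=pid, r=r, r_squared=r * r,
                              n_regions=n)


def pure_lesion_analysis(disc_profiles: Sequence[RegionProfile],
                         fmri_profile: RegionProfile,
                         effect_threshold: float = 0.5,
                         patient_ids: Sequence[str] | None = None,
                         lesions: Sequence[LesionMask] | None = None
                         ) -> TypicalLesionReport:
    """Correlate a cohort against the activation profile.

    ``pure_fraction`` is the percentage of valid patients whose r
    exceeds ``effect_threshold`` (one-sided, r > threshold). The top
    patient is the argmax of r; ties resolve to the lowest patient id
    (logged). If ``lesions`` is given (matching order), the top
    patient's mask is attached as the typical lesion.
    """
    if not 0.0 < effect_threshold < 1.0:
        raise ParameterError("effect_threshold must be in (0, 1)")
    if patient_ids is None:
        patient_ids = [p.source_tag or f"P{i:04d}"
                       for i, p in enumerate(disc_profiles)]
    if len(patient_ids) != len(disc_profiles):
        raise ParameterError("one patient id per profile required")
    if lesions is not None and len(lesions) != len(disc_profiles):
        raise ParameterError("one lesion per profile required")

    corrs = [patient_correlation(dp, fmri_profile, pid)
             for dp, pid in zip(disc_profiles, patient_ids)]
    valid = [c for c in corrs if c.valid]
    if len(valid) < 2:
        raise DegenerateDataError(
            f"only {len(valid)} patients have a defined correlation"
        )
    n_excluded = len(corrs) - len(valid)
    if n_excluded:
        log.warning("excluded %d patients with undefined correlations",
                    n_excluded)
    pure = sum(1 for c in valid if c.r > effect_threshold)
    pure_fraction = 100.0 * pure / len(valid)
    best_r = max(c.r for c in valid)
    tied = sorted((c for c in valid if c.r == best_r),
                  key=lambda c: c.patient_id)
    if len(tied) > 1:
        log.warning("top-patient tie at r=%.6f; keeping lowest id %s",
                    best_r, tied[0].patient_id)
    top = tied[0]
    typical = None
    if lesions is not None:
        by_id = {l.patient_id: l for l in lesions}
        typical = by_id.get(top.patient_id)
    return TypicalLesionReport(correlations=corrs,
                               pure_fraction=pure_fraction,
                               effect_threshold=effect_threshold,
                               top_patient=top,
                               n_excluded=n_excluded,
                               typical_lesion_map=typical)


def export_typical_lesion(report: TypicalLesionReport,
                          out_dir: str | os.PathLike) -> dict[str, str]:
    """Write typical_lesion.nii.gz, correlations.tsv and summary.json."""
    out_dir = str(out_dir)
    if not os.path.isdir(out_dir):
        raise IOError(f"output directory does not exist: {out_dir}")
    paths: dict[str, str] = {}

    rows = [{"patient_id": c.patient_id,
             "r": c.r,
             "r_squared": c.r_squared,
             "flag": "ok" if c.valid else f"excluded: {c.reason}"}
            for c in report.correlations]
    tsv = os.path.join(out_dir, "correlations.tsv")
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False,
                              float_format="%.10g")
    paths["correlations"] = tsv

    summary = {
        "pure_fraction_percent": report.pure_fraction,
        "effect_threshold": report.effect_threshold,
        "n_patients": len(report.correlations),
        "n_excluded": report.n_excluded,
        "top_patient": {
            "patient_id": report.top_patient.patient_id,
            "r": report.top_patient.r,
            "r_squared": report.top_patient.r_squared,
        },
    }
    js = os.path.join(out_dir, "summary.json")
    with open(js, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = js

    if report.typical_lesion_map is not None:
        nii = os.path.join(out_dir, "typical_lesion.nii.gz")
        save_volume(report.typical_lesion_map.mask, nii, dtype=np.int16)
        paths["typical_lesion"] = nii
    return paths
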