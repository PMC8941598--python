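"""In-memory containers shared across the pipeline.

A :class:`FeatureTable` bundles the intensity matrix (features x samples) with
feature metadata (m/z, retention time, assay, filter flags), sample metadata
(well, role, dose, injection order, apical endpoints) and an ordered audit trail
of filtering steps. Tables round-trip through plain TSV so every intermediate is
inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

# sample roles
ROLE_DOSE = "dose"
ROLE_NEG = "negative_control"
ROLE_POS = "positive_control"
ROLE_QC = "qc"
ROLE_BLANK = "blank"
ROLE_QC_BLANK = "qc_blank"

EMBRYO_ROLES = (ROLE_DOSE, ROLE_NEG, ROLE_POS)

FEATURE_META_COLS = ["mz", "rt_seconds", "assay"]
FILTER_FLAGS = [
    "qc_absent",
    "high_rsd",
    "below_noise_floor",
    "insource",
    "biotp_mass_match",
    "negative_intensity",
    "blank_dominated",
    "low_blank_ratio",
    "drift_uncorrectable",
]


@dataclass
class AuditEntry:
    step: str
    features_before: int
    features_after: int
    flagged: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "features_before": self.features_before,
            "features_after": self.features_after,
            "flagged": list(self.flagged),
        }


@dataclass
class FeatureTable:
    """Intensity matrix plus metadata and a filtering audit trail.

    intensities : DataFrame, index = feature_id, columns = sample_id
    features    : DataFrame, index = feature_id (mz, rt_seconds, assay, flags)
    samples     : DataFrame, index = sample_id (well, role, dose_group,
                  nominal_dose, injection_index, endpoint flags)
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    audit: list[AuditEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("feature metadata does not match intensity rows")
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not match intensity columns")
        if self.samples["injection_index"].duplicated().any():
            raise ValueError("injection_index must be unique within a run")

    # -- basic views -------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def samples_with_role(self, *roles: str) -> pd.Index:
        return self.samples.index[self.samples["role"].isin(roles)]

    @property
    def qc_samples(self) -> pd.Index:
        return self.samples_with_role(ROLE_QC)

    @property
    def blank_samples(self) -> pd.Index:
        return self.samples_with_role(ROLE_BLANK)

    @property
    def qc_blank_samples(self) -> pd.Index:
        return self.samples_with_role(ROLE_QC_BLANK)

    @property
    def embryo_samples(self) -> pd.Index:
        return self.samples_with_role(*EMBRYO_ROLES)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(),
            self.features.copy(),
            self.samples.copy(),
            list(self.audit),
        )

    # -- filtering ---------------------------------------------------------
    def drop_features(self, feature_ids, step: str, flag: str | None = None) -> "FeatureTable":
        """Remove features, record the step in the audit, set the flag column."""
        dropped = pd.Index(feature_ids)
        before = len(self.feature_ids)
        keep = ~self.feature_ids.isin(dropped)
        features = self.features.copy()
        if flag is not None:
            if flag not in features.columns:
                features[flag] = False
            features.loc[features.index.isin(dropped), flag] = True
        out = FeatureTable(
            self.intensities.loc[keep],
            features.loc[keep.values if hasattr(keep, "values") else keep],
            self.samples.copy(),
            list(self.audit),
        )
        out.audit.append(
            AuditEntry(step, before, len(out.feature_ids), sorted(map(str, dropped)))
        )
        return out

    def note_step(self, step: str, flagged: list[str] | None = None) -> None:
        n = len(self.feature_ids)
        self.audit.append(AuditEntry(step, n, n, flagged or []))

    # -- IO ------------------------------------------------------------------
    def to_tsv(self, feature_path: str | Path, sample_path: str | Path) -> None:
        """Write the feature-table contract: feature_id, mz, rt_seconds, assay,
        then one intensity column per sample_id; sample metadata separately."""
        meta = self.features[FEATURE_META_COLS]
        wide = pd.concat([meta, self.intensities], axis=1)
        wide.index.name = "feature_id"
        wide.to_csv(feature_path, sep="\t")
        samples = self.samples.copy()
        samples.index.name = "sample_id"
        samples.to_csv(sample_path, sep="\t")

    @classmethod
    def from_tsv(cls, feature_path: str | Path, sample_path: str | Path) -> "FeatureTable":
        wide = pd.read_csv(feature_path, sep="\t", index_col="feature_id")
        samples = pd.read_csv(sample_path, sep="\t", index_col="sample_id")
        meta = wide[FEATURE_META_COLS].copy()
        intensities = wide.drop(columns=FEATURE_META_COLS)
        intensities.columns = intensities.columns.astype(str)
        samples.index = samples.index.astype(str)
        intensities = intensities[samples.index]
        return cls(intensities, meta, samples)

    def audit_to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for entry in self.audit:
                fh.write(json.dumps(entry.to_dict()) + "\n")


def audit_counts(table: FeatureTable) -> list[tuple[str, int, int]]:
    return [(a.step, a.features_before, a.features_after) for a in table.audit]
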