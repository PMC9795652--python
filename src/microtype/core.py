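"""Core domain types shared by every analysis stage.

The pipeline's substrate is a samples × features abundance matrix
(:class:`FeatureTable`) carrying a level tag (otu, genus, species, pathway,
food, lipid), optional taxonomy strings, and a counts-vs-proportions flag.
Sample metadata, paired RNA/DNA pathway tables, and the run configuration
get their own small containers with explicit validation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LEVELS = ("otu", "genus", "species", "pathway", "food", "lipid")

#: tolerance for "rows sum to one" when detecting relative-abundance tables
_REL_TOL = 1e-9


class MicrotypeError(Exception):
    """Base class for all package errors."""


class ParseError(MicrotypeError):
    """Malformed input file (names the offending row/column where known)."""


class ValidationError(MicrotypeError):
    """Input violates a documented contract."""


@dataclass
class FeatureTable:
    """Samples × features abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample ids as index and feature ids as columns.
        Values must be non-negative and finite.
    level:
        One of ``otu, genus, species, pathway, food, lipid``.
    taxonomy:
        Optional mapping feature id -> lineage string.
    is_relative:
        True when each row is a composition summing to 1.
    """

    data: pd.DataFrame
    level: str
    taxonomy: dict[str, str] | None = None
    is_relative: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown table level {self.level!r}; expected one of {LEVELS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite abundance values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if self.is_relative:
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-6
            if bad.any():
                raise ValidationError(
                    f"relative table rows must sum to 1; offending samples: "
                    f"{self.data.index[bad].tolist()[:5]}"
                )

    # -- basic views -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    # -- transforms --------------------------------------------------------
    def relative(self) -> "FeatureTable":
        """Per-sample closure to proportions. Error on all-zero rows."""
        if self.is_relative:
            return self
        vals = self.values()
        sums = vals.sum(axis=1)
        if (sums <= 0).any():
            zero = self.data.index[sums <= 0].tolist()
            raise ValidationError(f"cannot normalize all-zero samples: {zero}")
        rel = pd.DataFrame(vals / sums[:, None], index=self.data.index, columns=self.data.columns)
        return FeatureTable(rel, self.level, self.taxonomy, is_relative=True)

    def subset_features(self, keep: Sequence[str]) -> "FeatureTable":
        """Column subset. Intentionally does NOT re-close proportions."""
        sub = self.data.loc[:, list(keep)]
        tax = {f: self.taxonomy[f] for f in keep if f in self.taxonomy} if self.taxonomy else None
        out = FeatureTable.__new__(FeatureTable)
        out.data = sub
        out.level = self.level
        out.taxonomy = tax
        # rows may no longer sum to 1 after dropping columns; keep the flag
        # false so downstream validation does not fire
        out.is_relative = False
        return out

    def subset_samples(self, keep: Sequence[str]) -> "FeatureTable":
        sub = self.data.loc[list(keep)]
        return FeatureTable(sub, self.level, self.taxonomy, is_relative=self.is_relative)


def detect_relative(df: pd.DataFrame) -> bool:
    """A table is taken as relative when every row sums to 1 ± 1e-9."""
    sums = df.to_numpy(dtype=float).sum(axis=1)
    return bool(np.all(np.abs(sums - 1.0) <= 1e-6))


METADATA_NUMERIC = (
    "bmi age fasting_glucose fasting_insulin glucose_auc insulin_auc "
    "glucose_mean insulin_mean tfeq_ue tfeq_cr tfeq_ee bite_symptom bite_severity "
    "yfas_symptoms pss energy_kcal_day fiber_g_day protein_g carb_g fat_g"
).split()


@dataclass
class SampleMetadata:
    """Per-sample host metadata.

    Wraps a DataFrame indexed by sample id.  ``weight_group`` is NW/OB;
    missing values stay as NaN (no imputation — statistical stages do
    complete-case analysis and report N).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        if "weight_group" in self.data.columns:
            groups = set(self.data["weight_group"].dropna().unique())
            if not groups <= {"NW", "OB"}:
                raise ValidationError(f"weight_group must be NW/OB, got {groups}")
        if {"yfas_symptoms", "yfas_diagnosis"} <= set(self.data.columns):
            sym = self.data["yfas_symptoms"]
            diag = self.data["yfas_diagnosis"].fillna(False).astype(bool)
            bad = diag & (sym < 3)
            if bad.any():
                raise ValidationError(
                    "yfas_diagnosis requires >= 3 symptoms; offending samples: "
                    f"{self.data.index[bad].tolist()}"
                )
        if "yfas_symptoms" in self.data.columns:
            sym = self.data["yfas_symptoms"].dropna()
            if (sym < 0).any():
                raise ValidationError("yfas_symptoms must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class PairedOmicsTable:
    """Paired RNA- and DNA-level pathway abundances.

    Row keys are ``pathway_id|species_id`` (plus unstratified totals keyed
    by pathway id alone); both tables share the same samples and keys.
    Zeros in the DNA table are kept, never dropped, so the ratio stage can
    apply its explicit zero policy.
    """

    rna: FeatureTable
    dna: FeatureTable

    def __post_init__(self) -> None:
        if list(self.rna.sample_ids) != list(self.dna.sample_ids):
            raise ValidationError("RNA and DNA tables must share the same samples, in order")
        if list(self.rna.feature_ids) != list(self.dna.feature_ids):
            missing = set(self.rna.feature_ids) ^ set(self.dna.feature_ids)
            raise ValidationError(f"RNA/DNA key mismatch: {sorted(missing)[:10]}")

    @property
    def keys(self) -> list[str]:
        return self.rna.feature_ids

    @staticmethod
    def split_key(key: str) -> tuple[str, str | None]:
        """'pathway|species' -> (pathway, species); bare pathway -> (pathway, None)."""
        if "|" in key:
            p, s = key.split("|", 1)
            return p, s
        return key, None


@dataclass
class AnalysisConfig:
    """Thresholds, sizes and seeds for every stage.

    All proportions are fractions in [0, 1].  ``rng_seed`` is mandatory for
    any stochastic stage; runs with the same config + seed are reproducible.
    """

    prevalence_threshold: float = 0.20
    genus_rel_abund_threshold: float = 0.001
    genus_min_samples: int = 2
    n_clusters: int | None = None        # None = auto by silhouette
    max_clusters: int = 8
    n_cags: int = 5
    n_diet_groups: int = 3
    n_permutations: int = 999
    fdr_alpha: float = 0.05
    rng_seed: int = 0
    shannon_log_base: float = 2.0
    spls_n_components: int = 2
    spls_keep_x: int | None = None       # None = dense (all features)
    weighted_unifrac_normalized: bool = True
    bh_valid_pair_fraction: float = 0.95
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("prevalence_threshold", "genus_rel_abund_threshold", "fdr_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_permutations < 99:
            raise ValidationError("n_permutations must be >= 99")
        if self.rng_seed is None:
            raise ValidationError("rng_seed is mandatory")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
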