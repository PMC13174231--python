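"""Site-specific irAE vocabularies: labels, synsets, ICI drug lists, organ categories.

Every institution annotates immune-related adverse events (irAEs) with its own
label granularity — one site may keep colitis and diarrhoea as separate labels
while another merges them under a single colitis label whose synset carries both
surface forms. A :class:`SiteProfile` captures one such site vocabulary in a
single YAML artifact so a run is reproducible from one file: the label list with
per-label synonym sets ("synsets"), the immune checkpoint inhibitor (ICI) drug
list, and the mapping from each label to one of ten fixed organ-level categories.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

logger = logging.getLogger(__name__)

#: Closed set of organ-level irAE categories.
CATEGORIES: frozenset[str] = frozenset(
    {
        "Cardiovascular",
        "Dermatologic",
        "Endocrine",
        "Gastrointestinal",
        "Haematological",
        "Musculoskeletal and Rheumatologic",
        "Neurologic",
        "Other",
        "Pulmonary",
        "Renal",
    }
)

#: Category used for labels missing from a profile's category map.
FALLBACK_CATEGORY = "Other"


def normalize_label_id(raw: str) -> str:
    """Lowercase a label identifier and collapse separators to underscores."""
    norm = re.sub(r"[\s\-/]+", "_", raw.strip().lower())
    norm = re.sub(r"[^a-z0-9_]", "", norm)
    return norm.strip("_")


class IrAELabel(BaseModel):
    """One irAE label: stable id, display name, and ordered synonym set."""

    model_config = ConfigDict(frozen=True)

    label_id: str
    display_name: str
    synset: tuple[str, ...] = ()

    @field_validator("label_id")
    @classmethod
    def _normalize_id(cls, v: str) -> str:
        norm = normalize_label_id(v)
        if not norm:
            raise ValueError(f"label_id {v!r} normalizes to an empty identifier")
        return norm

    @field_validator("display_name")
    @classmethod
    def _nonempty_display(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("display_name must be non-empty")
        return v

    @field_validator("synset")
    @classmethod
    def _nonempty_terms(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if any(not t.strip() for t in v):
            raise ValueError("synset entries must be non-empty strings")
        return v

    @property
    def surface_forms(self) -> tuple[str, ...]:
        """Display name followed by synset terms, synset order preserved."""
        return (self.display_name, *self.synset)


class SiteProfile(BaseModel):
    """A site's irAE vocabulary, ICI drug list, and label→category mapping."""

    model_config = ConfigDict(frozen=True)

    site_id: str
    labels: tuple[IrAELabel, ...]
    ici_drugs: tuple[str, ...]
    category_map: dict[str, str]

    @model_validator(mode="after")
    def _check(self) -> "SiteProfile":
        if not self.labels:
            raise ValueError("profile must define at least one irAE label")
        if not self.ici_drugs:
            raise ValueError("profile must list at least one ICI drug")
        ids = [lab.label_id for lab in self.labels]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate label_id(s): {sorted(dupes)}")
        names = [lab.display_name.lower() for lab in self.labels]
        dupe_names = {n for n in names if names.count(n) > 1}
        if dupe_names:
            raise ValueError(f"display_name reused across labels: {sorted(dupe_names)}")
        unknown = set(self.category_map) - set(ids)
        if unknown:
            raise ValueError(f"category_map references unknown label(s): {sorted(unknown)}")
        bad_cat = set(self.category_map.values()) - CATEGORIES
        if bad_cat:
            raise ValueError(
                f"category name(s) outside the closed set: {sorted(bad_cat)}"
            )
        return self

    @property
    def label_ids(self) -> tuple[str, ...]:
        return tuple(lab.label_id for lab in self.labels)

    def get_label(self, label_id: str) -> IrAELabel:
        for lab in self.labels:
            if lab.label_id == label_id:
                return lab
        raise KeyError(f"label {label_id!r} not in profile {self.site_id!r}")

    def category_of(self, label_id: str) -> str:
        """Category of a label; unmapped labels fall back to 'Other' with a warning."""
        if label_id not in set(self.label_ids):
            raise KeyError(f"label {label_id!r} not in profile {self.site_id!r}")
        cat = self.category_map.get(label_id)
        if cat is None:
            logger.warning(
                "label %r has no category in profile %r; assigning %r",
                label_id,
                self.site_id,
                FALLBACK_CATEGORY,
            )
            return FALLBACK_CATEGORY
        return cat

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "labels": [
                {
                    "label_id": lab.label_id,
                    "display_name": lab.display_name,
                    "synset": list(lab.synset),
                }
                for lab in self.labels
            ],
            "ici_drugs": list(self.ici_drugs),
            "category_map": dict(self.category_map),
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)
        )


def validate_label_set(labels: Iterable[str], profile: SiteProfile) -> frozenset[str]:
    """Validate a set of label ids against a profile; empty set means 'None'."""
    labels = frozenset(labels)
    unknown = labels - set(profile.label_ids)
    if unknown:
        raise ValueError(
            f"label(s) {sorted(unknown)} not defined in profile {profile.site_id!r}"
        )
    return labels


def load_site_profile(path: str | Path) -> SiteProfile:
    """Load and validate a site profile from a YAML file.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` (via
    pydantic) for any profile that violates the vocabulary invariants, so
    configuration problems surface before any pipeline stage runs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"site profile not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"profile file {path} does not hold a mapping")
    return SiteProfile(**data)


def builtin_profile_path(name: str) -> Path:
    """Filesystem path of a bundled example profile (``vumc``, ``ucsf``, ``roche``, ``demo``)."""
    ref = resources.files("iraescan") / "profiles" / f"{name.lower()}.yaml"
    p = Path(str(ref))
    if not p.exists():
        raise FileNotFoundError(f"no bundled profile named {name!r}")
    return p


def load_builtin_profile(name: str) -> SiteProfile:
    return load_site_profile(builtin_profile_path(name))


def map_to_categories(labels: Iterable[str], profile: SiteProfile) -> frozenset[str]:
    """Project a set of irAE labels to organ-level categories.

    Category positivity is the logical OR over member labels: the projected set
    is the union of the categories of each member, so ``|categories(S)| <= |S|``
    and the projection is monotone under set inclusion.
    """
    labels = validate_label_set(labels, profile)
    return frozenset(profile.category_of(lab) for lab in labels)
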