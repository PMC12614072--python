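"""B-ALL subtype label harmonization.

The default scheme encodes the 20-category taxonomy used for pediatric
B-cell acute lymphoblastic leukemia cohorts: rare "-like" categories are
merged into broader groups (ZNF384-like with ZNF384, KMT2A-like with
KMT2A), CRLF2(non-Ph-like) is excluded for insufficient sample size, and
samples annotated with two subtypes or as "other" are dropped. Each
harmonized subtype additionally belongs to one of four biological groups
(fusion gene, transcription-factor alteration, ploidy, rare subtype) used
for group-level performance rollups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "SubtypeScheme",
    "default_scheme",
    "harmonize_labels",
    "FUSION_GENE",
    "TF_ALTERATION",
    "PLOIDY",
    "RARE_SUBTYPE",
]

FUSION_GENE = "Fusion Gene"
TF_ALTERATION = "TF Alteration"
PLOIDY = "Ploidy"
RARE_SUBTYPE = "Rare Subtype"

# Raw labels matching these (case-insensitively) are ambiguous annotations,
# not subtypes, and are dropped.
_OTHER_LABELS = {"other", "others", "unknown"}

# Separators marking a sample annotated with two subtypes. "/" is NOT a
# separator: "BCL2/MYC" is a single subtype name.
_DUAL_SEPARATORS = (";", ",")


@dataclass(frozen=True)
class SubtypeScheme:
    """Label taxonomy: harmonized categories, merges, exclusions, groups."""

    labels: tuple[str, ...]
    merge_map: dict[str, str] = field(default_factory=dict)
    exclusions: frozenset[str] = field(default_factory=frozenset)
    group_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate harmonized labels")
        bad_targets = set(self.merge_map.values()) - set(self.labels)
        if bad_targets:
            raise ValueError(f"merge targets not in labels: {sorted(bad_targets)}")
        overlap = set(self.exclusions) & set(self.labels)
        if overlap:
            raise ValueError(f"excluded labels also listed as labels: {sorted(overlap)}")
        if self.group_map:
            missing = set(self.labels) - set(self.group_map)
            if missing:
                raise ValueError(f"labels without a group: {sorted(missing)}")

    def group_members(self, group: str) -> list[str]:
        return [lab for lab in self.labels if self.group_map.get(lab) == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            g = self.group_map.get(lab)
            if g is not None and g not in seen:
                seen.append(g)
        return seen


def default_scheme() -> SubtypeScheme:
    """The 20-subtype scheme with its merges, exclusion and four groups."""
    group_map = {
        # fusion-gene driven subtypes
        "Ph-like": FUSION_GENE,
        "Ph": FUSION_GENE,
        "ETV6-RUNX1": FUSION_GENE,
        "ETV6-RUNX1-like": FUSION_GENE,
        "KMT2A Group": FUSION_GENE,
        "TCF3-PBX1": FUSION_GENE,
        "DUX4": FUSION_GENE,
        "ZNF384 Group": FUSION_GENE,
        "MEF2D": FUSION_GENE,
        # transcription-factor alterations
        "PAX5alt": TF_ALTERATION,
        "PAX5 P80R": TF_ALTERATION,
        "IKZF1 N159Y": TF_ALTERATION,
        # ploidy shifts
        "High hyperdiploid": PLOIDY,
        "Low hypodiploid": PLOIDY,
        "Low hyperdiploid": PLOIDY,
        "Near haploid": PLOIDY,
        "iAMP21": PLOIDY,
        # rare subtypes
        "BCL2/MYC": RARE_SUBTYPE,
        "NUTM1": RARE_SUBTYPE,
        "HLF": RARE_SUBTYPE,
    }
    merge_map = {
        "ZNF384": "ZNF384 Group",
        "ZNF384-like": "ZNF384 Group",
        "KMT2A": "KMT2A Group",
        "KMT2A-like": "KMT2A Group",
    }
    return SubtypeScheme(
        labels=tuple(group_map),
        merge_map=merge_map,
        exclusions=frozenset({"CRLF2(non-Ph-like)"}),
        group_map=group_map,
    )


def harmonize_labels(
    raw_labels: Mapping[str, str],
    scheme: SubtypeScheme,
) -> tuple[dict[str, str], list[str]]:
    """Map raw per-sample labels onto a scheme's harmonized categories.

    Returns ``(kept, dropped)`` where ``kept`` maps sample id to
    harmonized label and ``dropped`` lists samples removed because their
    raw label is excluded, is an "other" annotation, or lists two
    subtypes. A raw label not covered by the scheme at all is an error
    (it usually means a typo or a scheme/cohort mismatch).
    """
    kept: dict[str, str] = {}
    dropped: list[str] = []
    for sample, raw in raw_labels.items():
        raw = str(raw).strip()
        if raw.lower() in _OTHER_LABELS:
            dropped.append(sample)
            continue
        if any(sep in raw for sep in _DUAL_SEPARATORS):
            dropped.append(sample)
            continue
        if raw in scheme.exclusions:
            dropped.append(sample)
            continue
        if raw in scheme.merge_map:
            kept[sample] = scheme.merge_map[raw]
        elif raw in scheme.labels:
            kept[sample] = raw
        else:
            raise ValueError(f"unrecognized subtype label {raw!r} for sample {sample!r}")
    return kept, dropped
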