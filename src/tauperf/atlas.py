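"""Brainnetome-246 region atlas and the hypoperfusion target-region set.

The bundled TSV fixture lists the 246 atlas regions (210 cortical, 36
subcortical; left/right interleaved) with their lobar compartment and
hemisphere.  Twenty-one regions are flagged as the established 4RT
hypoperfusion targets, together with the reported percent difference versus
healthy controls and the FDR-corrected p-value at which each was detected.
The full public nomenclature is used for the 225 non-target labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

COMPARTMENTS = frozenset({
    "Frontal lobe", "Temporal lobe", "Parietal lobe", "Occipital lobe",
    "Limbic", "Insula", "Basal ganglia", "Thalamus",
})

N_REGIONS = 246


@dataclass(frozen=True)
class RegionDef:
    """A single atlas region: short label, 1-based index, lobe, hemisphere."""

    label: str
    index: int
    compartment: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r} for {self.label!r}")
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be L or R, got {self.hemisphere!r}")
        if not self.label.endswith(f"_{self.hemisphere}"):
            raise ValueError(
                f"label {self.label!r} does not match hemisphere {self.hemisphere!r}"
            )


@dataclass(frozen=True)
class TargetRegionSet:
    """Regions with established disease-related hypoperfusion.

    ``percent_diff`` and ``p_fdr_reported`` hold, per label, the signed
    percent difference of patient versus control group means and the
    FDR-corrected p-value at which the region was originally detected.
    """

    labels: tuple[str, ...]
    percent_diff: dict[str, float]
    p_fdr_reported: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.labels) != set(self.percent_diff) or set(self.labels) != set(
            self.p_fdr_reported
        ):
            raise ValueError("percent_diff / p_fdr_reported keys must match labels")


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered collection of the 246 atlas regions; anchors column semantics."""

    entries: tuple[RegionDef, ...]
    targets: TargetRegionSet = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.entries) != N_REGIONS:
            raise ValueError(f"atlas must have {N_REGIONS} entries, got {len(self.entries)}")
        labels = [e.label for e in self.entries]
        if len(set(labels)) != N_REGIONS:
            raise ValueError("atlas labels must be unique")
        if [e.index for e in self.entries] != list(range(1, N_REGIONS + 1)):
            raise ValueError("atlas indices must run 1..246 in order")
        if self.targets is not None:
            unknown = set(self.targets.labels) - set(labels)
            if unknown:
                raise ValueError(f"target labels not in atlas: {sorted(unknown)}")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, label: str) -> RegionDef:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"region {label!r} not in atlas") from None

    @property
    def _by_label(self) -> dict[str, RegionDef]:
        # frozen dataclass: cache on the instance dict via object.__setattr__
        cache = self.__dict__.get("_label_cache")
        if cache is None:
            cache = {e.label: e for e in self.entries}
            object.__setattr__(self, "_label_cache", cache)
        return cache

    def compartment_of(self, label: str) -> str:
        return self[label].compartment

    def hemisphere_of(self, label: str) -> str:
        return self[label].hemisphere

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionAtlas":
        df = pd.read_csv(path, sep="\t", dtype={"is_table2_target": int})
        entries = tuple(
            RegionDef(label=lab, index=int(idx), compartment=comp, hemisphere=hemi)
            for idx, lab, comp, hemi in zip(
                df["index"], df["label"], df["compartment"], df["hemisphere"]
            )
        )
        tgt = df[df["is_table2_target"] == 1]
        targets = TargetRegionSet(
            labels=tuple(tgt["label"]),
            percent_diff=dict(zip(tgt["label"], tgt["table2_percent_diff"].astype(float))),
            p_fdr_reported=dict(zip(tgt["label"], tgt["table2_p_fdr"].astype(float))),
        )
        return cls(entries=entries, targets=targets)


@lru_cache(maxsize=1)
def load_atlas() -> RegionAtlas:
    """Load the bundled 246-region atlas (cached)."""
    with resources.as_file(
        resources.files("tauperf.data").joinpath("brainnetome246.tsv")
    ) as path:
        return RegionAtlas.from_tsv(path)
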