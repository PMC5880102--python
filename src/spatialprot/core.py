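"""Domain types shared across pipeline stages.

All tabular data is carried in :class:`pandas.DataFrame` containers wrapped by
thin dataclasses that enforce the invariants each stage relies on.  Missing
values are represented as ``NaN`` in memory and as the literal ``NA`` on disk;
they are never silently coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """A parsed table violates a domain invariant."""


#: Metadata columns of a PSM table, in canonical order.  Every remaining
#: column is interpreted as a reporter-ion intensity channel.
PSM_META_COLUMNS = (
    "peptide_id",
    "protein_group",
    "proteotypic",
    "is_contaminant",
    "is_decoy",
)

#: Region labels understood by the design table.
REGIONS = (
    "tumor",
    "peritumor",
    "center",
    "periphery",
    "TS1",
    "TS2",
    "TS3",
    "capsule",
    "control",
)


@dataclass
class PsmTable:
    """PSM-level rows with per-channel reporter intensities and identity flags.

    ``df`` holds the metadata columns of :data:`PSM_META_COLUMNS` followed by
    one float column per channel.  Intensities must be finite and >= 0.
    Multiple PSMs of the same peptide are allowed.
    """

    df: pd.DataFrame
    channels: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in PSM_META_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"PSM table missing required column(s): {missing}")
        absent = [c for c in self.channels if c not in self.df.columns]
        if absent:
            raise FormatError(f"PSM table missing intensity column(s): {absent}")
        inten = self.df[self.channels].to_numpy(dtype=float)
        if not np.all(np.isfinite(inten)):
            bad = np.argwhere(~np.isfinite(inten))
            raise ValidationError(
                f"non-finite intensity at row {int(bad[0, 0])}, "
                f"channel {self.channels[int(bad[0, 1])]}"
            )
        if np.any(inten < 0):
            bad = np.argwhere(inten < 0)
            raise ValidationError(
                f"negative intensity at row {int(bad[0, 0])}, "
                f"channel {self.channels[int(bad[0, 1])]}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def intensities(self) -> pd.DataFrame:
        """Intensity sub-matrix (rows x channels), positionally indexed."""
        return self.df[self.channels]


@dataclass
class DesignTable:
    """Mapping channel -> (patient, region) for one plex."""

    mapping: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for ch, (patient, region) in self.mapping.items():
            if region not in REGIONS:
                raise ValidationError(
                    f"unknown region {region!r} for channel {ch!r}; "
                    f"expected one of {REGIONS}"
                )

    @property
    def channels(self) -> list[str]:
        return list(self.mapping)

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for patient, _ in self.mapping.values():
            seen.setdefault(patient, None)
        return list(seen)

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, region in self.mapping.values():
            seen.setdefault(region, None)
        return list(seen)

    def channel_for(self, patient: str, region: str) -> str:
        """Return the unique channel assigned to (patient, region)."""
        hits = [
            ch
            for ch, (p, r) in self.mapping.items()
            if p == patient and r == region
        ]
        if not hits:
            raise KeyError(f"no channel for patient={patient!r} region={region!r}")
        if len(hits) > 1:
            raise ValidationError(
                f"multiple channels for patient={patient!r} region={region!r}: {hits}"
            )
        return hits[0]

    def channels_for_region(self, region: str) -> list[str]:
        return [ch for ch, (_, r) in self.mapping.items() if r == region]


@dataclass
class ProteinMatrix:
    """Protein-group x sample matrix of transformed abundances.

    ``values`` is indexed by protein group with one column per sample
    (channel id or sample id); ``n_peptides`` counts the distinct peptides
    contributing to each protein.  Missing entries are ``NaN``.
    """

    values: pd.DataFrame
    n_peptides: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.n_peptides.index):
            raise ValidationError("values and n_peptides must share an index")
        if (self.n_peptides < 1).any():
            raise ValidationError("n_peptides must be >= 1")
        finite_or_nan = np.isfinite(self.values.to_numpy(dtype=float)) | self.values.isna().to_numpy()
        if not finite_or_nan.all():
            raise ValidationError("protein matrix contains non-finite values")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AnnotationSet:
    """Per-protein subcellular compartment label and gene-set memberships."""

    compartment: dict[str, str] = field(default_factory=dict)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)

    def terms_for(self, protein: str) -> set[str]:
        return {t for t, members in self.gene_sets.items() if protein in members}

    def proteins_in_compartment(self, label: str) -> set[str]:
        return {p for p, c in self.compartment.items() if c == label}


@dataclass
class QpcrTable:
    """qPCR Ct measurements: one row per (sample, gene, replicate).

    The on-disk format stores one measurement per row; replicate lists are
    reassembled via :meth:`replicates`.
    """

    df: pd.DataFrame  # columns: sample, gene, ct

    def __post_init__(self) -> None:
        required = ["sample", "gene", "ct"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"qPCR table missing required column(s): {missing}")
        ct = self.df["ct"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ct)) or np.any(ct <= 0) or np.any(ct >= 45):
            raise ValidationError("Ct values must be finite and in (0, 45)")

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.df["sample"]:
            seen.setdefault(s, None)
        return list(seen)

    def genes_for(self, sample: str) -> set[str]:
        return set(self.df.loc[self.df["sample"] == sample, "gene"])

    def replicates(self, sample: str, gene: str) -> list[float]:
        sel = (self.df["sample"] == sample) & (self.df["gene"] == gene)
        return [float(v) for v in self.df.loc[sel, "ct"]]


def make_psm_table(rows: Iterable[Mapping], channels: list[str]) -> PsmTable:
    """Build a validated :class:`PsmTable` from dict-like rows.

    Each row supplies the metadata fields plus an ``intensities`` mapping
    channel -> value.
    """
    records = []
    for row in rows:
        rec = {k: row[k] for k in PSM_META_COLUMNS}
        for ch in channels:
            rec[ch] = float(row["intensities"][ch])
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=list(PSM_META_COLUMNS) + channels)
    return PsmTable(df=df, channels=channels)
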