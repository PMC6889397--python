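"""Reading, writing and harmonizing expression views and clinical tables.

A cohort is represented as a :class:`MultiViewDataset`: one or more expression
"views" (RNA-seq quantified two ways, microarray, optionally aCGH log-ratios)
measured on an identical, identically ordered sample list, plus a clinical
table carrying survival endpoints and risk covariates.  Files on disk follow
the conventions of public neuroblastoma cohort deposits: tab-separated
expression matrices with gene identifiers in the first column and sample
identifiers in the header row, and CSV clinical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    HarmonizationError,
    SampleLookupError,
    ValidationError,
)

__all__ = [
    "ExpressionView",
    "ClinicalTable",
    "MultiViewDataset",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "harmonize_genes",
    "flip_acgh_signs",
    "REQUIRED_CLINICAL_COLUMNS",
]

REQUIRED_CLINICAL_COLUMNS = (
    "os_event",
    "os_time",
    "efs_event",
    "efs_time",
    "high_risk",
    "mycn_amplified",
    "age",
    "stage",
)


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class ExpressionView:
    """One molecular data type over a cohort, stored samples x genes (log2 scale).

    Parameters
    ----------
    name : str
        Free label for the view (e.g. ``"rnaseq-mav"``).
    platform : str
        Platform tag; ``"acgh"`` marks copy-number log-ratio views, which are
        the only views eligible for sign correction.
    genes, samples : list of str
        Ordered identifier lists matching the matrix axes.
    values : ndarray, shape (n_samples, n_genes)
    """

    name: str
    platform: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValidationError(
                f"view {self.name!r}: matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"view {self.name!r}: non-finite value at sample "
                f"{self.samples[i]!r}, gene {self.genes[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)

    def restrict_genes(self, genes: Sequence[str]) -> "ExpressionView":
        """Return a copy restricted to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise HarmonizationError(
                f"view {self.name!r} lacks genes: {missing[:5]}"
            )
        cols = [index[g] for g in genes]
        return replace(self, genes=list(genes), values=self.values[:, cols])

    def restrict_samples(self, samples: Sequence[str]) -> "ExpressionView":
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise SampleLookupError(f"view {self.name!r} lacks samples: {missing[:5]}")
        rows = [index[s] for s in samples]
        return replace(self, samples=list(samples), values=self.values[rows])


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations: OS/EFS endpoints and risk covariates.

    ``data`` is indexed by sample identifier and carries the columns listed in
    :data:`REQUIRED_CLINICAL_COLUMNS`.  ``mycn_amplified`` may contain missing
    values (coded as missing, never as 0); all other binary columns must be
    strictly 0/1 and both time columns nonnegative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers in clinical table")
        missing_cols = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"clinical table missing columns: {missing_cols}")
        for col in ("os_event", "efs_event", "high_risk"):
            vals = df[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(f"column {col!r} must be binary 0/1")
        for col in ("os_time", "efs_time", "age"):
            vals = pd.to_numeric(df[col]).to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or (vals < 0).any():
                raise ValidationError(f"column {col!r} must be finite and nonnegative")
        mycn = df["mycn_amplified"]
        observed = mycn.dropna()
        if not observed.isin((0, 1)).all():
            raise ValidationError("mycn_amplified must be 0/1 or missing")
        # normalize mycn to a nullable integer column
        self.data = df.assign(mycn_amplified=mycn.astype("Int64"))

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise SampleLookupError(f"clinical table lacks samples: {missing[:5]}")
        return ClinicalTable(self.data.loc[list(samples)])


@dataclass
class MultiViewDataset:
    """Aligned expression views plus (optionally) a clinical table.

    Every view shares the clinical table's sample list, identically ordered;
    this is the unit of analysis consumed by the kernel and clustering layers.
    """

    views: list[ExpressionView]
    clinical: ClinicalTable | None = None

    def __post_init__(self) -> None:
        if not self.views:
            raise ValidationError("a dataset needs at least one view")
        ref = self.views[0].samples
        for v in self.views[1:]:
            if v.samples != ref:
                raise ValidationError(
                    f"view {v.name!r} sample list differs from view {self.views[0].name!r}"
                )
        if self.clinical is not None and self.clinical.samples != ref:
            raise ValidationError("clinical sample list differs from view sample list")
        names = [v.name for v in self.views]
        _check_unique(names, "view")

    @property
    def samples(self) -> list[str]:
        return self.views[0].samples

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def view_names(self) -> list[str]:
        return [v.name for v in self.views]

    def view(self, name: str) -> ExpressionView:
        for v in self.views:
            if v.name == name:
                return v
        raise KeyError(f"no view named {name!r}")

    def subset_samples(self, samples: Sequence[str]) -> "MultiViewDataset":
        views = [v.restrict_samples(samples) for v in self.views]
        clinical = self.clinical.subset(samples) if self.clinical is not None else None
        return MultiViewDataset(views, clinical)


def read_expression(
    path: str | Path,
    platform: str,
    *,
    name: str | None = None,
    samples_as_rows: bool = False,
) -> ExpressionView:
    """Read a TSV expression matrix into an :class:`ExpressionView`.

    Files are genes x samples by default (first column gene identifiers, header
    row sample identifiers); pass ``samples_as_rows=True`` for the transposed
    layout.  The returned view is always oriented samples x genes.  Duplicate
    gene rows are collapsed by their arithmetic mean.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV matrix: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    if df.index.isnull().any() or any(str(c).strip() == "" for c in df.columns):
        raise FormatError(f"{path}: malformed header or identifier column")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if samples_as_rows:
        numeric = numeric.T  # now genes x samples, like the default layout
    # collapse duplicated gene identifiers by mean, keeping first-occurrence order
    if numeric.index.has_duplicates:
        order = list(dict.fromkeys(numeric.index))
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionView(
        name=name or path.stem,
        platform=platform,
        genes=[str(g) for g in numeric.index],
        samples=[str(s) for s in numeric.columns],
        values=numeric.to_numpy(dtype=float).T,
    )


def write_expression(view: ExpressionView, path: str | Path) -> None:
    """Write a view as a genes x samples TSV that round-trips exactly."""
    df = pd.DataFrame(view.values.T, index=view.genes, columns=view.samples)
    df.to_csv(Path(path), sep="\t", float_format="%.17g", index_label="gene")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical CSV (one row per sample, ``sample_id`` column required)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: clinical table needs a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(Path(path), index_label="sample_id")


def harmonize_genes(
    a: MultiViewDataset, b: MultiViewDataset
) -> tuple[MultiViewDataset, MultiViewDataset]:
    """Restrict two cohorts to their shared genes, in one canonical sorted order.

    Matching is by exact identifier string.  The intersection is taken across
    every view of both cohorts so that all views end up on an identical gene
    list; an empty intersection raises :class:`HarmonizationError`.
    """
    sets = [set(v.genes) for v in a.views] + [set(v.genes) for v in b.views]
    shared = sorted(set.intersection(*sets))
    if not shared:
        raise HarmonizationError("no genes shared between the two cohorts")
    a2 = MultiViewDataset([v.restrict_genes(shared) for v in a.views], a.clinical)
    b2 = MultiViewDataset([v.restrict_genes(shared) for v in b.views], b.clinical)
    return a2, b2


def flip_acgh_signs(view: ExpressionView, sample_ids: Sequence[str]) -> ExpressionView:
    """Multiply the listed samples' aCGH log-ratio rows by -1.

    This is the tumor/normal label correction: for the affected patients the
    intensity signs were recorded reversed, so their whole profiles flip.
    Applying the correction twice restores the original matrix.
    """
    if view.platform != "acgh":
        raise ValidationError(
            f"sign flips apply to aCGH views only, got platform {view.platform!r}"
        )
    index = {s: i for i, s in enumerate(view.samples)}
    missing = [s for s in sample_ids if s not in index]
    if missing:
        raise SampleLookupError(f"unknown sample ids: {missing}")
    values = view.values.copy()
    rows = [index[s] for s in sample_ids]
    values[rows] *= -1.0
    return replace(view, values=values)


def read_sample_list(path: str | Path) -> list[str]:
    """Read a plain-text file of sample ids, one per line (sign-flip lists)."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]
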