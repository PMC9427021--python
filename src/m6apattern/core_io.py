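"""Domain types, file readers/writers, cohort merging and validation.

All downstream stages consume the containers defined here:

* :class:`ExpressionMatrix` — a log2-scale gene-by-sample matrix backed by a
  :class:`pandas.DataFrame` (genes in rows, samples in columns).
* sample metadata — a plain :class:`pandas.DataFrame` with a fixed schema,
  validated by :func:`validate_metadata`.
* :class:`GeneSetCollection` — named gene sets (GMT dialect on disk).
* regulator panel — the 20-gene m6A regulator list (8 writers, 2 erasers,
  10 readers) bundled as package data.

Expression values are assumed to be on a log2 scale already (normalised
array intensities or log2 FPKM); no internal log transform is applied.
Gene identifiers are matched case-sensitively with no alias resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DISEASE_STATUSES = ("RA", "HC")
TREATMENTS = ("infliximab", "rituximab", "none")
RESPONSES = ("responder", "non_responder")

#: DAS28-ESR / DAS28-CRP above this value denotes high disease activity.
DAS28_HIGH_ACTIVITY = 5.1

METADATA_COLUMNS = (
    "sample_id",
    "disease_status",
    "cohort_id",
    "das28_esr",
    "das28_crp",
    "treatment",
    "response",
)


class ValidationError(ValueError):
    """Raised when an input container violates its declared invariants."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes in rows and samples in columns.

    Wraps a DataFrame whose index holds gene identifiers and whose columns
    hold sample identifiers. Identifiers must be unique and every cell must
    be finite.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame
        if not isinstance(frame, pd.DataFrame):
            frame = pd.DataFrame(frame)
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups}")
        if frame.columns.has_duplicates:
            dups = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        values = frame.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{frame.index[bad[0]]!r}, sample {frame.columns[bad[1]]!r}"
            )
        self.frame = frame.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.frame.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.frame.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.frame.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.frame[list(samples)])

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets with optional per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def restrict_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Filter every set to ``universe``; drop sets that become empty."""
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            filtered = [g for g in genes if g in uni]
            if filtered:
                kept[name] = filtered
            else:
                logger.warning("gene set %r has no gene in the universe; dropped", name)
        return GeneSetCollection(kept, {k: v for k, v in self.descriptions.items() if k in kept})

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class AnalysisConfig:
    """Tunable thresholds and sizes for the full analysis.

    Defaults follow the conventions of the upstream tools each stage mirrors
    (70/30 split, SMOTE k=5, 500 consensus subsamples at 80%, ssGSEA weight
    0.25, DEG cutoff p < 0.05, Boruta at alpha 0.01).
    """

    split_fraction: float = 0.7
    smote_k: int = 5
    consensus_h: int = 500
    consensus_p_item: float = 0.8
    k_min: int = 2
    k_max: int = 6
    base_method: str = "hclust_pearson"
    linkage: str = "average"
    delta_threshold: float = 0.1
    ssgsea_alpha: float = 0.25
    deg_p_cut: float = 0.05
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.01
    n_trees: int = 500
    r_min: float = 0.3
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValidationError("split_fraction must lie in (0, 1)")
        if self.smote_k < 1:
            raise ValidationError("smote_k must be >= 1")
        if self.consensus_h < 1:
            raise ValidationError("consensus_h must be >= 1")
        if not 0 < self.consensus_p_item <= 1:
            raise ValidationError("consensus_p_item must lie in (0, 1]")
        if not 2 <= self.k_min <= self.k_max:
            raise ValidationError("need 2 <= k_min <= k_max")
        if self.base_method not in ("kmeans", "hclust_pearson"):
            raise ValidationError(f"unknown base_method {self.base_method!r}")
        if self.ssgsea_alpha <= 0:
            raise ValidationError("ssgsea_alpha must be > 0")
        if not 0 < self.deg_p_cut < 1:
            raise ValidationError("deg_p_cut must lie in (0, 1)")
        if self.boruta_max_iter < 1 or not 0 < self.boruta_alpha < 1:
            raise ValidationError("invalid Boruta parameters")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from YAML (or JSON, a YAML subset) keyed by field name."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column gene ids, header samples).

    Duplicate gene rows are collapsed by their mean (logged); a duplicate
    sample id or any non-numeric cell is an error naming the offending cell.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValidationError(f"duplicate sample identifiers in {path}: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"non-numeric value {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {path}"
        )
    if numeric.index.has_duplicates:
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        logger.info("collapsing duplicate gene rows by mean: %s", dups)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric)


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Within-set duplicate genes are removed keeping the first occurrence.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, *genes = parts
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if not deduped:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata CSV."""
    meta = pd.read_csv(path, dtype={"sample_id": str, "cohort_id": str})
    return validate_metadata(meta)


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check schema, uniqueness and value ranges of a metadata table."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    meta = meta.loc[:, list(METADATA_COLUMNS)].copy()
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id in metadata: {dups}")
    bad_status = set(meta["disease_status"].dropna()) - set(DISEASE_STATUSES)
    if bad_status:
        raise ValidationError(f"unknown disease_status values: {sorted(bad_status)}")
    for col in ("das28_esr", "das28_crp"):
        vals = pd.to_numeric(meta[col], errors="coerce")
        present = meta[col].notna() & (meta[col].astype(str).str.len() > 0)
        if ((vals < 0) & present).any() or (vals[present].isna()).any():
            raise ValidationError(f"{col} must be finite and >= 0 where present")
        meta[col] = vals
    bad_treat = set(meta["treatment"].dropna()) - set(TREATMENTS)
    if bad_treat:
        raise ValidationError(f"unknown treatment values: {sorted(bad_treat)}")
    bad_resp = set(meta["response"].dropna()) - set(RESPONSES)
    if bad_resp:
        raise ValidationError(f"unknown response values: {sorted(bad_resp)}")
    return meta


def _read_bundled_csv(name: str) -> pd.DataFrame:
    with resources.files("m6apattern.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def default_regulator_panel() -> pd.DataFrame:
    """The bundled 20-gene m6A regulator panel.

    Eight writers (methyltransferase complex members), two erasers
    (demethylases) and ten readers (m6A-binding proteins).
    """
    panel = _read_bundled_csv("regulator_panel.csv")
    assert len(panel) == 20 and set(panel["regulator_class"]) == {"writer", "eraser", "reader"}
    return panel


def default_hla_panel() -> list[str]:
    """Bundled HLA gene list for high/low score-group comparisons."""
    return _read_bundled_csv("hla_panel.csv")["gene_id"].tolist()


def default_checkpoint_panel() -> list[str]:
    """Bundled 12-gene immune-checkpoint list (TNFSF15, TNFRSF14, CTLA4, CD86, ...)."""
    return _read_bundled_csv("checkpoint_panel.csv")["gene_id"].tolist()


# ---------------------------------------------------------------------------
# cohort merging


def merge_cohorts(
    matrices: Sequence[ExpressionMatrix],
    metadata: pd.DataFrame,
    scale_within_cohort: bool = False,
) -> ExpressionMatrix:
    """Concatenate cohorts on the intersection of their gene sets.

    With ``scale_within_cohort`` each gene is z-scored within each cohort
    (sample standard deviation, ddof=1) before concatenation — a
    deterministic, assumption-light stand-in for cross-platform batch
    correction. Constant genes within a cohort map to zero.
    """
    if not matrices:
        raise ValidationError("need at least one expression matrix")
    metadata = validate_metadata(metadata)
    meta_samples = set(metadata["sample_id"])
    seen: set[str] = set()
    for m in matrices:
        overlap = seen & set(m.sample_ids)
        if overlap:
            raise ValidationError(f"sample ids shared between matrices: {sorted(overlap)}")
        seen |= set(m.sample_ids)
        uncovered = set(m.sample_ids) - meta_samples
        if uncovered:
            raise ValidationError(f"samples missing from metadata: {sorted(uncovered)}")

    common = list(matrices[0].gene_ids)
    common_set = set(common)
    for m in matrices[1:]:
        common_set &= set(m.gene_ids)
    common = [g for g in common if g in common_set]
    if not common:
        raise ValidationError("gene intersection across cohorts is empty")

    cohort_of = dict(zip(metadata["sample_id"], metadata["cohort_id"]))
    pieces = []
    for m in matrices:
        frame = m.frame.loc[common]
        if scale_within_cohort:
            cohorts = pd.Series([cohort_of[s] for s in frame.columns], index=frame.columns)
            scaled = []
            for _, cols in frame.T.groupby(cohorts, sort=False):
                block = cols.T  # genes x cohort samples
                mu = block.mean(axis=1)
                sd = block.std(axis=1, ddof=1)
                z = block.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
                scaled.append(z)
            frame = pd.concat(scaled, axis=1)[frame.columns]
        pieces.append(frame)
    merged = pd.concat(pieces, axis=1)
    return ExpressionMatrix(merged)
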