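"""Readers, writers, and validated in-memory types for on-disk artifacts.

All matrices travel as :class:`OmicsMatrix` (features x samples), sample
metadata as :class:`SampleSheet`, CpG-to-gene maps as
:class:`CpGAnnotation`, and gene sets as :class:`GeneSetCollection`.
Dialects are deliberately plain: TSV matrices with a "." decimal separator
and no quoting, a CSV sample sheet, the standard GMT gene-set format, and
TSV result tables with six significant digits.  Feature and sample
identifiers are opaque strings (no case folding).  Missing values are not
supported: arrays are complete after upstream preprocessing, so an empty
cell is an error rather than an NA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from responderomics.errors import DataError, FormatError

logger = logging.getLogger(__name__)

BETA_EPS = 1e-6

GROUPS = ("LRE", "RES")
TIMEPOINTS = ("w0", "w10")
SEXES = ("F", "M")
REGIONS = ("promoter", "body", "intergenic")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """Dense features x samples matrix for one omics layer.

    ``layer`` is ``"expression_log2"`` (log2 array intensities) or
    ``"methylation_beta"`` (beta values, strictly inside (0, 1)).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    layer: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.layer not in ("expression_log2", "methylation_beta"):
            raise DataError(f"unknown layer {self.layer!r}")
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.layer == "methylation_beta":
            if (self.values <= 0).any() or (self.values >= 1).any():
                bad = np.argwhere((self.values <= 0) | (self.values >= 1))[0]
                raise DataError(
                    f"beta value outside (0, 1) at feature "
                    f"{self.feature_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, features: Sequence[str]) -> "OmicsMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in features if f not in idx]
        if missing:
            raise DataError(f"features not in matrix: {missing[:5]}")
        rows = [idx[f] for f in features]
        return OmicsMatrix(list(features), list(self.sample_ids), self.values[rows], self.layer)

    def subset_samples(self, samples: Sequence[str]) -> "OmicsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise DataError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return OmicsMatrix(list(self.feature_ids), list(samples), self.values[:, cols], self.layer)


@dataclass
class SampleSheet:
    """Per-sample metadata: subject, responder group, timepoint, sex, Matsuda.

    Each subject contributes at most one sample per timepoint (the paired
    pre/post biopsy design).  Matsuda columns may be NaN when the phenotype
    is supplied separately.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "group", "timepoint", "sex")

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"sample sheet missing required column {col!r}")
        for col in ("matsuda_pre", "matsuda_post"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise")
        _check_unique(df["sample_id"].tolist(), "sample_id")
        for col, allowed in (("group", GROUPS), ("timepoint", TIMEPOINTS), ("sex", SEXES)):
            bad = sorted(set(df[col]) - set(allowed))
            if bad:
                raise FormatError(
                    f"unknown {col} value(s) {bad}; allowed: {{{', '.join(allowed)}}}"
                )
        dup = df.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            row = df[dup].iloc[0]
            raise FormatError(
                f"subject {row['subject_id']!r} has more than one {row['timepoint']} sample"
            )
        for col in ("matsuda_pre", "matsuda_post"):
            vals = df[col]
            if ((vals <= 0) & vals.notna()).any():
                bad_id = df.loc[(vals <= 0) & vals.notna(), "sample_id"].iloc[0]
                raise FormatError(f"non-positive {col} for sample {bad_id!r}")
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.table["subject_id"]))

    def samples_for(self, group: str | None = None, timepoint: str | None = None) -> list[str]:
        df = self.table
        if group is not None:
            df = df[df["group"] == group]
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        return df["sample_id"].tolist()

    def subject_group(self) -> dict[str, str]:
        return dict(zip(self.table["subject_id"], self.table["group"]))

    def subject_outcome(self) -> dict[str, float]:
        """Matsuda fold change (post/pre) per subject."""
        out: dict[str, float] = {}
        for _, row in self.table.drop_duplicates("subject_id").iterrows():
            out[row["subject_id"]] = float(row["matsuda_post"]) / float(row["matsuda_pre"])
        return out


@dataclass
class CpGAnnotation:
    """CpG-to-gene mapping with 1-based positions (Infinium manifest convention)."""

    table: pd.DataFrame

    REQUIRED = ("cpg_id", "chrom", "pos", "gene_id", "region")

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"CpG annotation missing required column {col!r}")
        df["gene_id"] = df["gene_id"].fillna("").astype(str)
        _check_unique(df["cpg_id"].tolist(), "cpg_id")
        df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
        if (df["pos"] < 1).any():
            bad = df.loc[df["pos"] < 1, "cpg_id"].iloc[0]
            raise FormatError(f"position < 1 for CpG {bad!r}")
        bad_region = sorted(set(df["region"]) - set(REGIONS))
        if bad_region:
            raise FormatError(
                f"unknown region value(s) {bad_region}; allowed: {{{', '.join(REGIONS)}}}"
            )
        empty_gene = df["gene_id"] == ""
        intergenic = df["region"] == "intergenic"
        if (empty_gene & ~intergenic).any():
            bad = df.loc[empty_gene & ~intergenic, "cpg_id"].iloc[0]
            raise FormatError(f"CpG {bad!r} has region != intergenic but no gene_id")
        if (~empty_gene & intergenic).any():
            bad = df.loc[~empty_gene & intergenic, "cpg_id"].iloc[0]
            raise FormatError(f"intergenic CpG {bad!r} must have empty gene_id")
        self.table = df


@dataclass
class GeneSetCollection:
    """Named gene sets: term_id -> (description, member genes)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_desc, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {term!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {term!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def genes(self, term: str) -> list[str]:
        return self.sets[term][1]

    def description(self, term: str) -> str:
        return self.sets[term][0]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r}")
        seen.add(x)


def _read_matrix_tsv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header must contain a feature column and >= 1 sample")
        sample_ids = header[1:]
        _check_unique(sample_ids, "sample id")
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, found {len(parts)}"
                )
            feature_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError:
                for col, x in enumerate(parts[1:], start=2):
                    try:
                        float(x)
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}, column {col}: non-numeric cell {x!r}"
                        ) from None
                raise
        _check_unique(feature_ids, "feature id")
    return feature_ids, sample_ids, np.asarray(rows, dtype=float)


def read_expression(path: str | Path) -> OmicsMatrix:
    """Read a genes x samples TSV of log2 expression values.

    First column holds feature ids, header row holds sample ids; file order
    is preserved.
    """
    feature_ids, sample_ids, values = _read_matrix_tsv(path)
    return OmicsMatrix(feature_ids, sample_ids, values, layer="expression_log2")


def read_methylation(path: str | Path) -> tuple[OmicsMatrix, int]:
    """Read a CpGs x samples TSV of beta values.

    Values must lie in [0, 1]; exact 0/1 cells (a legitimate artifact of
    rounded array exports) are clipped to ``[BETA_EPS, 1 - BETA_EPS]`` and
    the clip count is logged and returned alongside the matrix.
    """
    feature_ids, sample_ids, values = _read_matrix_tsv(path)
    if (values < 0).any() or (values > 1).any():
        bad = np.argwhere((values < 0) | (values > 1))[0]
        raise FormatError(
            f"beta value outside [0, 1] at feature {feature_ids[bad[0]]!r}, "
            f"sample {sample_ids[bad[1]]!r}: {values[bad[0], bad[1]]}"
        )
    clipped = np.clip(values, BETA_EPS, 1.0 - BETA_EPS)
    n_clipped = int((clipped != values).sum())
    if n_clipped:
        logger.info("clipped %d beta cells to [%g, 1-%g]", n_clipped, BETA_EPS, BETA_EPS)
    return OmicsMatrix(feature_ids, sample_ids, clipped, layer="methylation_beta"), n_clipped


def read_samplesheet(path: str | Path) -> SampleSheet:
    """Read a CSV sample sheet (sample, subject, group, timepoint, sex, Matsuda)."""
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error plumbing
        raise FormatError(f"{path}: {exc}") from exc
    return SampleSheet(df)


def read_cpg_annotation(path: str | Path) -> CpGAnnotation:
    """Read a TSV CpG annotation (cpg_id, chrom, pos, gene_id, region)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return CpGAnnotation(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read the standard tab-separated GMT format: term, description, genes..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and >= 1 gene"
                )
            term, desc, genes = parts[0], parts[1], parts[2:]
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt(x: object) -> str:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "nan"
        return f"{x:.6g}"
    if isinstance(x, (bool, np.bool_)):
        return "True" if x else "False"
    return str(x)


def write_matrix(matrix: OmicsMatrix, path: str | Path, float_fmt: str = "%.10g") -> None:
    """Write an :class:`OmicsMatrix` as TSV (feature id first, sample header)."""
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=float_fmt)


def write_table(result: object, path: str | Path) -> None:
    """Write any result type as a TSV with a stable column order.

    Floats are rendered with 6 significant digits, so re-reading reproduces
    values to that precision.  Accepts a DataFrame directly or any result
    object exposing ``to_frame()``.
    """
    if isinstance(result, pd.DataFrame):
        df = result
    elif hasattr(result, "to_frame"):
        df = result.to_frame()
    else:
        raise DataError(f"cannot serialize object of type {type(result).__name__}")
    path = Path(path)
    with path.open("w") as fh:
        cols = list(df.columns)
        if df.index.name is not None:
            cols = [df.index.name] + cols
            fh.write("\t".join(cols) + "\n")
            for idx, row in df.iterrows():
                fh.write("\t".join([_fmt(idx)] + [_fmt(v) for v in row]) + "\n")
        else:
            fh.write("\t".join(cols) + "\n")
            for _, row in df.iterrows():
                fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term, (desc, genes) in collection:
            fh.write("\t".join([term, desc, *genes]) + "\n")
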