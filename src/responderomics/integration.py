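"""Promoter-methylation / expression integration.

Links differential methylation to differential expression: a DEG counts as
putatively epigenetically regulated when enough of its mapped CpGs are
differentially methylated in the matching contrast, optionally requiring
at least one promoter CpG whose methylation effect opposes the expression
effect (the classic inverse promoter relation).  The criterion behind
published "fraction regulated" figures varies between studies, so every
knob (CpG count, region filter, inverse requirement, p threshold) is
explicit configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from responderomics.diff_analysis import DiffResult
from responderomics.errors import ConfigError, DataError
from responderomics.io_formats import CpGAnnotation

logger = logging.getLogger(__name__)


@dataclass
class IntegrationResult:
    """Per-DEG methylation support and the summary regulated fraction."""

    table: pd.DataFrame  # index gene_id: supported, n_dm_cpgs, supporting_cpgs, inverse_promoter
    supported_count: int
    deg_count: int

    @property
    def fraction(self) -> float:
        return self.supported_count / self.deg_count

    def to_frame(self) -> pd.DataFrame:
        return self.table


def map_cpgs_to_genes(
    annotation: CpGAnnotation, region_filter: str = "all"
) -> dict[str, list[str]]:
    """gene_id -> CpG ids, restricted to ``region_filter`` (all | promoter).

    Intergenic CpGs are never mapped (they carry no gene).  Genes absent
    from the annotation simply do not appear in the mapping.
    """
    if region_filter not in ("all", "promoter"):
        raise ConfigError(f"region_filter must be 'all' or 'promoter', got {region_filter!r}")
    df = annotation.table
    df = df[df["region"] != "intergenic"]
    if region_filter == "promoter":
        df = df[df["region"] == "promoter"]
    mapping: dict[str, list[str]] = {}
    for cpg, gene in zip(df["cpg_id"], df["gene_id"]):
        mapping.setdefault(gene, []).append(cpg)
    return mapping


def flag_epigenetic_regulation(
    deg_list: list[str],
    dm_result: DiffResult,
    mapping: dict[str, list[str]],
    expression_effects: pd.Series | None = None,
    *,
    min_cpgs: int = 1,
    p_threshold: float = 0.05,
    require_inverse_promoter: bool = False,
    promoter_cpgs: dict[str, list[str]] | None = None,
) -> IntegrationResult:
    """Flag DEGs whose methylation changes could explain their expression change.

    A DEG is supported iff at least ``min_cpgs`` of its mapped CpGs are
    differentially methylated (p <= ``p_threshold`` in ``dm_result``).
    With ``require_inverse_promoter``, a supporting promoter CpG must in
    addition have a methylation effect whose sign opposes the gene's
    expression effect (``expression_effects`` then becomes mandatory, and
    ``promoter_cpgs`` supplies the promoter-restricted mapping).  DEGs
    absent from the mapping are counted unsupported with a log entry.
    """
    if not deg_list:
        raise DataError("deg_list is empty")
    if require_inverse_promoter and expression_effects is None:
        raise ConfigError("require_inverse_promoter needs per-gene expression effects")
    dm = dm_result.table
    dm_sig = dm[dm["p_value"] <= p_threshold]
    dm_effect = dm_sig["beta_hat"]
    sig_set = set(dm_sig.index)

    rows = []
    supported_count = 0
    unmapped = 0
    for gene in deg_list:
        cpgs = mapping.get(gene, [])
        if not cpgs:
            unmapped += 1
        dm_cpgs = [c for c in cpgs if c in sig_set]
        supported = len(dm_cpgs) >= min_cpgs
        inverse = False
        if supported and require_inverse_promoter:
            promoters = set((promoter_cpgs or mapping).get(gene, []))
            expr_sign = np.sign(expression_effects.get(gene, 0.0))
            inverse = any(
                c in promoters and np.sign(dm_effect[c]) == -expr_sign and expr_sign != 0
                for c in dm_cpgs
            )
            supported = inverse
        if supported:
            supported_count += 1
        rows.append(
            {
                "gene_id": gene,
                "supported": supported,
                "n_dm_cpgs": len(dm_cpgs),
                "supporting_cpgs": ",".join(dm_cpgs),
                "inverse_promoter": inverse,
            }
        )
    if unmapped:
        logger.info("%d DEG(s) without mapped CpGs counted unsupported", unmapped)
    table = pd.DataFrame(rows).set_index("gene_id")
    return IntegrationResult(
        table=table, supported_count=supported_count, deg_count=len(deg_list)
    )


def marker_methylation_support(
    markers: list[str],
    dm_result: DiffResult,
    mapping_promoter: dict[str, list[str]],
    expression_effects: pd.Series | None = None,
    *,
    min_cpgs: int = 2,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Markers with >= ``min_cpgs`` differentially methylated promoter CpGs.

    Each supported marker is annotated with its DM promoter CpGs and, when
    expression effects are supplied, the direction relation (inverse:
    higher expression with lower promoter methylation, or parallel).
    """
    dm = dm_result.table
    dm_sig = dm[dm["p_value"] <= p_threshold]
    sig_set = set(dm_sig.index)
    rows = []
    for gene in markers:
        dm_cpgs = [c for c in mapping_promoter.get(gene, []) if c in sig_set]
        if len(dm_cpgs) < min_cpgs:
            continue
        relation = ""
        if expression_effects is not None and gene in expression_effects.index:
            expr_sign = np.sign(expression_effects[gene])
            meth_signs = {np.sign(dm_sig.loc[c, "beta_hat"]) for c in dm_cpgs}
            if meth_signs == {-expr_sign}:
                relation = "inverse"
            elif meth_signs == {expr_sign}:
                relation = "parallel"
            else:
                relation = "mixed"
        rows.append(
            {
                "gene_id": gene,
                "n_dm_promoter_cpgs": len(dm_cpgs),
                "dm_promoter_cpgs": ",".join(dm_cpgs),
                "direction_relation": relation,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_dm_promoter_cpgs", "dm_promoter_cpgs", "direction_relation"]
    )
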