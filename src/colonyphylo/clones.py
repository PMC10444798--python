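"""Clonal-expansion detection, driver annotation and clonality summaries.

A post-embryonic clonal expansion is any clade of >= 2 colonies whose
common ancestor sits strictly beyond 75 mutations of molecular time from
the start of the tree — by birth a lineage has typically acquired ~50-65
mutations, so such clades must have expanded during postnatal life.
Driver screening is annotation-based: nonsynonymous or truncating variants
in a configurable gene list (SDS-associated genes plus known clonal
haematopoiesis / haematological cancer genes), and LOH/CNA intervals
covering dosage-sensitive loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .errors import DataError
from .phylo import MutationTree

__all__ = [
    "ExpansionRecord",
    "detect_expansions",
    "load_driver_config",
    "annotate_drivers",
    "summarize_clonality",
    "ClonalitySummary",
]


@dataclass
class ExpansionRecord:
    node: int
    tips: tuple
    n_tips: int
    mrca_height: float  # mutations of molecular time from tree start
    mrca_age_ci: tuple | None = None  # filled from the timing module if available
    drivers: list = field(default_factory=list)


def detect_expansions(
    mtree: MutationTree, threshold: float = 75.0, min_tips: int = 2,
    use_corrected: bool = True,
) -> list[ExpansionRecord]:
    """Maximal clades of >= min_tips colonies with MRCA strictly after ``threshold``.

    Heights use sensitivity-corrected branch lengths when available
    (``use_corrected=False`` falls back to raw counts); nested qualifying
    clades are reported only at their outermost ancestor.
    """
    tree = mtree.tree
    lengths = mtree.lengths if use_corrected else mtree.raw_count.astype(float)
    heights = tree.node_heights(lengths)
    out: list[ExpansionRecord] = []
    stack = [0]
    while stack:
        i = stack.pop()
        if len(tree.clade[i]) >= min_tips and heights[i] > threshold and tree.children[i]:
            out.append(
                ExpansionRecord(
                    node=i,
                    tips=tuple(sorted(tree.clade[i])),
                    n_tips=len(tree.clade[i]),
                    mrca_height=float(heights[i]),
                )
            )
            continue  # nested qualifying clades collapse into this one
        stack.extend(tree.children[i])
    return sorted(out, key=lambda r: r.node)


def load_driver_config(path=None) -> dict:
    """Load the driver screen config (packaged default if ``path`` is None)."""
    if path is None:
        text = resources.files("colonyphylo.data").joinpath("drivers.yaml").read_text()
    else:
        text = open(path).read()
    return yaml.safe_load(text)


def annotate_drivers(
    sites: pd.DataFrame,
    config: dict | None = None,
    assignments: pd.DataFrame | None = None,
    cna_regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag driver mutations among annotated sites.

    ``sites`` needs gene and consequence columns. Returns one row per
    driver with columns gene, driver_class, consequence and (when
    ``assignments`` is given) the branch node. LOH/CNA intervals
    overlapping a configured dosage locus are reported with class
    "dosage CNA".
    """
    cfg = config or load_driver_config()
    missing = {"gene", "consequence"} - set(sites.columns)
    if missing:
        raise DataError(f"site table lacks annotation columns: {sorted(missing)}")
    tokens = [t.lower() for t in cfg.get("nonsynonymous_tokens", [])]
    classes = {}
    for g in cfg.get("ch_cancer", []):
        classes[g] = "CH/cancer gene"
    for g in cfg.get("sds_associated", []):
        classes[g] = "SDS-associated"  # takes precedence over the CH list
    rows = []
    for sid, gene, csq in zip(sites.index, sites["gene"], sites["consequence"]):
        if not isinstance(gene, str) or gene not in classes:
            continue
        csq = str(csq).lower()
        if not any(t in csq for t in tokens):
            continue
        rows.append(
            {
                "site_id": sid,
                "gene": gene,
                "driver_class": classes[gene],
                "consequence": csq,
                "node": (
                    int(assignments.loc[sid, "node"])
                    if assignments is not None and sid in assignments.index
                    else pd.NA
                ),
            }
        )
    if cna_regions is not None:
        for _, r in cna_regions.iterrows():
            for dr in cfg.get("dosage_regions", []):
                if (
                    str(r["chrom"]) == str(dr["chrom"])
                    and int(r["start"]) <= int(dr["end"])
                    and int(r["end"]) >= int(dr["start"])
                ):
                    rows.append(
                        {
                            "site_id": f"cna:{r['chrom']}:{r['start']}-{r['end']}",
                            "gene": dr["gene"],
                            "driver_class": "dosage CNA",
                            "consequence": "loh/cna",
                            "node": pd.NA,
                            "colony": r.get("colony", pd.NA),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["site_id", "gene", "driver_class", "consequence", "node", "colony"]
    ).set_index("site_id")


@dataclass
class ClonalitySummary:
    n_colonies: int
    frac_in_expansion: float
    frac_with_driver: float
    union_fraction: float
    n_expanded_lineages: int  # expansions + singleton driver lineages


def summarize_clonality(
    mtree: MutationTree,
    expansions: list[ExpansionRecord],
    drivers: pd.DataFrame,
) -> ClonalitySummary:
    """Oligoclonality summary for one individual's tree.

    Driver rows with a branch node contribute that branch's clade of
    colonies; single driver colonies outside any detected expansion count
    as additional (small) expanded lineages.
    """
    tree = mtree.tree
    n = len(tree.tips)
    exp_tips = set()
    for e in expansions:
        exp_tips |= set(e.tips)
    driver_clades = []
    for _, row in drivers.iterrows():
        if pd.isna(row.get("node")):
            continue
        driver_clades.append(frozenset(tree.clade[int(row["node"])]))
    drv_tips = set().union(*driver_clades) if driver_clades else set()
    union = exp_tips | drv_tips
    exp_sets = [frozenset(e.tips) for e in expansions]
    extra = {dc for dc in driver_clades if not any(dc <= es for es in exp_sets)}
    return ClonalitySummary(
        n_colonies=n,
        frac_in_expansion=len(exp_tips) / n,
        frac_with_driver=len(drv_tips) / n,
        union_fraction=len(union) / n,
        n_expanded_lineages=len(exp_sets) + len(extra),
    )
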