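"""Per-tissue analysis orchestration and significance-matrix reporting.

``run_pipeline`` walks each requested tissue through the full analysis:
extract the tissue network, classify nodes, compute centralities, run
the random-set resampling comparison for each configured
(small class, background class, parameter) cell, compute TCR and
connected-TF means for the miRNA classes, Fisher neighbor enrichments,
class-association tests, and global network statistics.  Results come
back as tidy tables plus a manifest recording the seeds that make every
cell independently re-derivable; ``PipelineResult.write`` emits
byte-stable TSVs.

A failure in one tissue is logged and recorded; other tissues proceed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .network import (
    GeneClass,
    NodeType,
    RegulatoryNetwork,
    classify_nodes,
    partition_map,
    write_network,
)
from .stats import (
    SetComparisonResult,
    class_association,
    compare_sets,
    connected_tf_count,
    neighbor_enrichment,
    tcr,
)
from .tissue import extract_tissue_network
from .topology import MEASURES, centrality_profile, global_stats

__all__ = ["PipelineResult", "run_pipeline", "extract_subnetwork",
           "DEFAULT_COMPARISONS"]

logger = logging.getLogger(__name__)

#: (small set, background) class pairs tested per tissue, mirroring the
#: TS-vs-trivial, HK-vs-trivial, TS-vs-HK and disease-vs-non-disease
#: comparisons of the analysis.
DEFAULT_COMPARISONS: tuple[tuple[GeneClass, GeneClass], ...] = (
    (GeneClass.TS_TF, GeneClass.TRIVIAL_TF),
    (GeneClass.HK_TF, GeneClass.TRIVIAL_TF),
    (GeneClass.TS_TF, GeneClass.HK_TF),
    (GeneClass.DISEASE_TF, GeneClass.NONDISEASE_TF),
    (GeneClass.TS_MIRNA, GeneClass.TRIVIAL_MIRNA),
    (GeneClass.DISEASE_MIRNA, GeneClass.NONDISEASE_MIRNA),
)

#: Focal classes checked for TF/miRNA neighbor enrichment.
DEFAULT_ENRICHMENT_FOCI = (
    GeneClass.TS_TF,
    GeneClass.HK_TF,
    GeneClass.DISEASE_TF,
)

_FLOAT_FMT = "%.10g"


def _cell_seed(root_seed: int, index: int) -> int:
    """Deterministic per-cell seed below 2**31, re-derivable from the
    manifest (root seed + cell index)."""
    return int(
        np.random.SeedSequence([root_seed, index]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""

    significance: pd.DataFrame
    tcr_table: pd.DataFrame
    enrichment: pd.DataFrame
    global_stats_table: pd.DataFrame
    manifest: dict
    comparisons_detail: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def significance_matrix(self) -> pd.DataFrame:
        """Sparse Tables-1-3-style view: direction marks only, one row
        per tissue, one column per (comparison, parameter)."""
        if self.significance.empty:
            return pd.DataFrame()
        wide = self.significance.pivot_table(
            index="tissue",
            columns=["comparison", "parameter"],
            values="direction",
            aggfunc="first",
        )
        return wide.where(wide != "NONE", "")

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.significance.to_csv(
            out_dir / "significance_matrix.tsv",
            sep="\t",
            index=False,
            float_format=_FLOAT_FMT,
        )
        self.tcr_table.to_csv(
            out_dir / "tcr.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
        self.enrichment.to_csv(
            out_dir / "enrichment.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
        self.global_stats_table.to_csv(
            out_dir / "global_stats.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
        (out_dir / "manifest.yaml").write_text(
            yaml.safe_dump(self.manifest, sort_keys=True)
        )


def run_pipeline(
    ref: RegulatoryNetwork,
    tissues: list[str] | None = None,
    comparisons: tuple = DEFAULT_COMPARISONS,
    parameters: tuple = MEASURES,
    n_resamples: int = 2000,
    alpha: float = 0.10,
    fisher_alpha: float = 0.05,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full topological analysis over the given tissues.

    ``alpha`` (default 0.10) is the significance level of the
    resampling test; ``fisher_alpha`` (default 0.05) is recorded in the
    manifest as the level for Fisher enrichment calls.  All resampling
    seeds derive deterministically from ``seed`` and the cell index.
    """
    if tissues is None:
        tissues = sorted(ref.tissues())
    sig_rows: list[dict] = []
    tcr_rows: list[dict] = []
    enr_rows: list[dict] = []
    gs_rows: list[dict] = []
    detail: dict = {}
    failures: dict[str, str] = {}
    skipped: list[dict] = []
    cell_seeds: dict[str, int] = {}
    cell_index = 0

    for tissue in tissues:
        try:
            net = extract_tissue_network(ref, tissue)
            classes = partition_map(classify_nodes(net, tissue))
            profile = centrality_profile(net, measures=parameters)

            # -- resampling comparisons ---------------------------------
            for small_cls, bg_cls in comparisons:
                small = classes[GeneClass(small_cls)]
                bg = classes[GeneClass(bg_cls)]
                comparison = f"{GeneClass(small_cls).value}_vs_{GeneClass(bg_cls).value}"
                for parameter in parameters:
                    cell = f"{tissue}/{comparison}/{parameter}"
                    cseed = _cell_seed(seed, cell_index)
                    cell_index += 1
                    if not small or not bg or len(bg) < len(small):
                        skipped.append(
                            {
                                "cell": cell,
                                "reason": (
                                    f"sizes small={len(small)}, "
                                    f"background={len(bg)}"
                                ),
                            }
                        )
                        continue
                    res = compare_sets(
                        profile,
                        small,
                        bg,
                        parameter,
                        n_resamples=n_resamples,
                        alpha=alpha,
                        seed=cseed,
                    )
                    cell_seeds[cell] = cseed
                    detail[(tissue, comparison, parameter)] = res
                    sig_rows.append(
                        {
                            "tissue": tissue,
                            "comparison": comparison,
                            "parameter": parameter,
                            "n_small": len(small),
                            "n_background": len(bg),
                            "observed_mean": res.observed_mean,
                            "null_mean": float(res.null_means.mean()),
                            "p_greater": res.p_greater,
                            "p_less": res.p_less,
                            "direction": res.significant_direction.value,
                            "seed": cseed,
                        }
                    )

            # -- TCR + connected-TF means for miRNA classes -------------
            for cls in (GeneClass.TS_MIRNA, GeneClass.TRIVIAL_MIRNA):
                members = classes[cls]
                usable = sorted(
                    m for m in members if net.out_neighbors(m)
                )
                n_dropped = len(members) - len(usable)
                if n_dropped:
                    skipped.append(
                        {
                            "cell": f"{tissue}/tcr/{cls.value}",
                            "reason": (
                                f"{n_dropped} miRNA(s) with no expressed "
                                "target excluded from TCR"
                            ),
                        }
                    )
                if len(usable) < 2:
                    skipped.append(
                        {
                            "cell": f"{tissue}/tcr/{cls.value}",
                            "reason": f"only {len(usable)} usable miRNAs",
                        }
                    )
                    continue
                res = tcr(net, usable)
                tcr_rows.append(
                    {
                        "tissue": tissue,
                        "gene_class": cls.value,
                        "n_mir": res.n_mir,
                        "mean_out_degree": res.mean_out_degree,
                        "mean_target_number": res.mean_target_number,
                        "tcr": res.tcr,
                        "mean_connected_tfs": connected_tf_count(
                            net, usable
                        ),
                    }
                )

            # -- Fisher neighbor enrichment + class association ---------
            for focal_cls in DEFAULT_ENRICHMENT_FOCI:
                focal = classes[focal_cls]
                if not focal:
                    continue
                for ntype in (NodeType.TF, NodeType.MIRNA):
                    res = neighbor_enrichment(net, focal, ntype)
                    enr_rows.append(
                        {
                            "tissue": tissue,
                            "test": "neighbor_enrichment",
                            "focal_class": focal_cls.value,
                            "target_class": ntype.value,
                            "a": res.contingency[0][0],
                            "b": res.contingency[0][1],
                            "c": res.contingency[1][0],
                            "d": res.contingency[1][1],
                            "odds_ratio": res.odds_ratio,
                            "p_value": res.p_value,
                        }
                    )
            tf_universe = set(net.nodes_of_type(NodeType.TF))
            mir_universe = set(net.nodes_of_type(NodeType.MIRNA))
            assoc_specs = [
                (GeneClass.DISEASE_TF, GeneClass.TS_TF, tf_universe),
                (GeneClass.DISEASE_TF, GeneClass.HK_TF, tf_universe),
                (GeneClass.DISEASE_MIRNA, GeneClass.TS_MIRNA, mir_universe),
            ]
            parts = {p.class_name: p for p in classify_nodes(net, tissue)}
            for cls_a, cls_b, universe in assoc_specs:
                if not universe:
                    continue
                res = class_association(parts[cls_a], parts[cls_b], universe)
                enr_rows.append(
                    {
                        "tissue": tissue,
                        "test": "class_association",
                        "focal_class": cls_a.value,
                        "target_class": cls_b.value,
                        "a": res.contingency[0][0],
                        "b": res.contingency[0][1],
                        "c": res.contingency[1][0],
                        "d": res.contingency[1][1],
                        "odds_ratio": res.odds_ratio,
                        "p_value": res.p_value,
                    }
                )

            # -- global statistics --------------------------------------
            gs = global_stats(net)
            gs_rows.append(
                {
                    "tissue": tissue,
                    "n_nodes": net.n_nodes,
                    "n_edges": net.n_edges,
                    "characteristic_path_length": (
                        gs.characteristic_path_length
                    ),
                    "mean_in_degree": gs.mean_in_degree,
                    "mean_out_degree": gs.mean_out_degree,
                    "mean_betweenness": gs.mean_betweenness,
                    "mean_cluster_coefficient": (
                        gs.mean_cluster_coefficient
                    ),
                }
            )
        except Exception as exc:  # per-tissue isolation
            logger.warning("tissue %s failed: %s", tissue, exc)
            failures[tissue] = str(exc)

    manifest = {
        "package_version": _pkg_version,
        "seed": int(seed),
        "n_resamples": int(n_resamples),
        "alpha": float(alpha),
        "fisher_alpha": float(fisher_alpha),
        "tissues": list(tissues),
        "comparisons": [
            f"{GeneClass(a).value}_vs_{GeneClass(b).value}"
            for a, b in comparisons
        ],
        "parameters": list(parameters),
        "cell_seeds": cell_seeds,
        "skipped": skipped,
        "failures": dict(failures),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    sig_cols = [
        "tissue", "comparison", "parameter", "n_small", "n_background",
        "observed_mean", "null_mean", "p_greater", "p_less", "direction",
        "seed",
    ]
    result = PipelineResult(
        significance=pd.DataFrame(sig_rows, columns=sig_cols),
        tcr_table=pd.DataFrame(
            tcr_rows,
            columns=[
                "tissue", "gene_class", "n_mir", "mean_out_degree",
                "mean_target_number", "tcr", "mean_connected_tfs",
            ],
        ),
        enrichment=pd.DataFrame(
            enr_rows,
            columns=[
                "tissue", "test", "focal_class", "target_class",
                "a", "b", "c", "d", "odds_ratio", "p_value",
            ],
        ),
        global_stats_table=pd.DataFrame(
            gs_rows,
            columns=[
                "tissue", "n_nodes", "n_edges",
                "characteristic_path_length", "mean_in_degree",
                "mean_out_degree", "mean_betweenness",
                "mean_cluster_coefficient",
            ],
        ),
        manifest=manifest,
        comparisons_detail=detail,
        failures=failures,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def extract_subnetwork(
    net: RegulatoryNetwork,
    regulator_set,
    include_regulators_of: bool = False,
) -> RegulatoryNetwork:
    """Induced subnetwork of a regulator set, its targets, and
    optionally the regulators of the set (for hub-centred views).

    With a set of tissue-specific miRNAs having disjoint targets this
    yields the fan components seen in miRNA-module figures; with a
    single TF and ``include_regulators_of=True`` it yields the
    hub-plus-upstream-miRNAs view.
    """
    regs = set(regulator_set)
    if not regs:
        raise ValueError("regulator_set must be nonempty")
    for rid in regs:
        if rid not in net:
            raise KeyError(f"unknown node {rid!r}")
    keep = set(regs)
    for rid in regs:
        keep |= net.out_neighbors(rid)
        if include_regulators_of:
            keep |= net.in_neighbors(rid)
    nodes = [net.node(nid) for nid in sorted(keep)]
    edges = [(u, v) for u, v in net.edges if u in keep and v in keep]
    return RegulatoryNetwork(nodes, edges, tissue=net.tissue)
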