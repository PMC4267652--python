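"""Intersection of the two inference arms and evaluation against truth.

An interaction (CM, HM) enters the final signed bipartite network only
when both arms propose it: the CM passed the elastic-net deviation rule
for that HM, and the pair survived the SPCN's cross-validated
significance filter. The edge sign comes from the partial correlation
(conditioned on everything else, hence closest to direct); the
elastic-net sign is kept as provenance, with a concordance flag — edges
where the arms disagree on sign are flagged, not dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ParameterError, SchemaError
from .elastic_net import ElasticNetSelection, run_elastic_net_arm
from .spcn import BipartiteEdge, build_spcn, extract_hm_cm_edges
from .signal_matrix import (
    SignalMatrix,
    average_replicates,
    filter_promoters,
    log_standardize,
    median_ratio_normalize,
)
from .synthetic import TruthNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionEdge:
    cm: str
    hm: str
    sign: str  # from the partial correlation
    en_coef_mean: float
    pcor: float
    sign_concordant: bool


@dataclass
class InteractionNetwork:
    """Final signed bipartite CM-HM network with provenance."""

    edges: list[InteractionEdge]
    provenance: dict = field(default_factory=dict)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.cm, e.hm) for e in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


def intersect_arms(
    en: dict[str, ElasticNetSelection],
    spcn_edges: list[BipartiteEdge],
    provenance: dict | None = None,
) -> InteractionNetwork:
    """Keep (CM, HM) pairs proposed by both arms.

    Raises a schema error if the SPCN edges mention HMs or CMs the
    elastic-net arm has never seen (the arms must share one matrix).
    """
    en_cms = set().union(*(sel.coef_mean.index for sel in en.values())) if en else set()
    for edge in spcn_edges:
        if edge.hm not in en or edge.cm not in en_cms:
            raise SchemaError(
                f"SPCN edge ({edge.cm}, {edge.hm}) outside the elastic-net "
                "track universe; both arms must run on the same matrix"
            )
    edges = []
    for edge in spcn_edges:
        sel = en[edge.hm]
        selected_cms = {cm for cm, _ in sel.selected}
        if edge.cm not in selected_cms:
            continue
        en_coef = float(sel.coef_mean[edge.cm])
        en_sign = "+" if en_coef >= 0 else "-"
        edges.append(
            InteractionEdge(
                cm=edge.cm,
                hm=edge.hm,
                sign=edge.sign,
                en_coef_mean=en_coef,
                pcor=edge.rho,
                sign_concordant=en_sign == edge.sign,
            )
        )
    return InteractionNetwork(
        edges=sorted(edges, key=lambda e: (e.hm, e.cm)),
        provenance=dict(provenance or {}),
    )


@dataclass
class EvaluationResult:
    """Recovery metrics of an inferred network against a known truth."""

    precision: float | None  # None when nothing was recovered
    recall: float
    sign_accuracy: float | None
    n_recovered: int
    n_true: int
    n_true_positive: int


def evaluate_against_truth(
    network: InteractionNetwork,
    truth: TruthNetwork,
    restrict_recall_to: set[tuple[str, str]] | None = None,
) -> EvaluationResult:
    """Precision / recall / sign accuracy of recovered (CM, HM) edges.

    ``restrict_recall_to`` limits the recall denominator (and numerator)
    to a subset of true edges, e.g. the top weight-magnitude tercile.
    Precision is undefined (None) for an empty recovered set; sign
    accuracy is the fraction of true-positive edges whose sign matches
    the sign of the true weight.
    """
    known = set(truth.cm_names) | set(truth.hm_names)
    for e in network.edges:
        if e.cm not in truth.cm_names or e.hm not in truth.hm_names:
            raise SchemaError(
                f"edge ({e.cm}, {e.hm}) has tracks outside the truth "
                f"network universe of {len(known)} tracks"
            )
    true_edges = truth.true_edges()
    recovered = network.edge_pairs()
    tp = recovered & true_edges

    recall_universe = (
        true_edges if restrict_recall_to is None else set(restrict_recall_to)
    )
    recall_hits = recovered & recall_universe
    recall = len(recall_hits) / len(recall_universe) if recall_universe else 0.0

    if recovered:
        precision = len(tp) / len(recovered)
    else:
        precision = None
    if tp:
        sign_by_pair = {(e.cm, e.hm): e.sign for e in network.edges}
        correct = sum(
            1
            for cm, hm in tp
            if sign_by_pair[(cm, hm)]
            == ("+" if truth.edge_weight(cm, hm) > 0 else "-")
        )
        sign_accuracy = correct / len(tp)
    else:
        sign_accuracy = None
    return EvaluationResult(
        precision=precision,
        recall=recall,
        sign_accuracy=sign_accuracy,
        n_recovered=len(recovered),
        n_true=len(true_edges),
        n_true_positive=len(tp),
    )


# -- serialization --------------------------------------------------------

_TSV_COLUMNS = ["cm", "hm", "sign", "en_coef_mean", "pcor", "sign_concordant"]


def write_network(
    network: InteractionNetwork, path: str | Path, fmt: str = "tsv"
) -> None:
    """Write the network as a TSV edge list, SIF, or GraphML."""
    path = Path(path)
    if fmt == "tsv":
        rows = [
            {
                "cm": e.cm,
                "hm": e.hm,
                "sign": e.sign,
                "en_coef_mean": repr(e.en_coef_mean),
                "pcor": repr(e.pcor),
                "sign_concordant": e.sign_concordant,
            }
            for e in network.edges
        ]
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        lines = [
            f"{e.cm}\t{'activates' if e.sign == '+' else 'represses'}\t{e.hm}"
            for e in network.edges
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(to_graph(network), path)
    else:
        raise ParameterError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str = "tsv") -> InteractionNetwork:
    """Read a TSV edge list written by ``write_network``."""
    if fmt != "tsv":
        raise ParameterError("only the TSV edge list round-trips")
    table = pd.read_csv(path, sep="\t", dtype={"sign": str})
    edges = [
        InteractionEdge(
            cm=row["cm"],
            hm=row["hm"],
            sign=row["sign"],
            en_coef_mean=float(row["en_coef_mean"]),
            pcor=float(row["pcor"]),
            sign_concordant=bool(row["sign_concordant"]),
        )
        for _, row in table.iterrows()
    ]
    return InteractionNetwork(edges=edges)


def to_graph(network: InteractionNetwork) -> nx.Graph:
    """Bipartite graph view (CM nodes vs HM nodes) of the network."""
    g = nx.Graph()
    for e in network.edges:
        g.add_node(e.cm, kind="CM", bipartite=0)
        g.add_node(e.hm, kind="HM", bipartite=1)
        g.add_edge(
            e.cm,
            e.hm,
            sign=e.sign,
            en_coef_mean=e.en_coef_mean,
            pcor=e.pcor,
            sign_concordant=e.sign_concordant,
        )
    return g


# -- end-to-end convenience ------------------------------------------------


def preprocess(
    matrix: SignalMatrix,
    replicate_groups: dict[str, list[str]] | None = None,
) -> SignalMatrix:
    """Raw counts to analysis-ready: filter, normalize, average, log/z.

    Expression replicates default to one group averaging all expression
    tracks into ``expression``.
    """
    if replicate_groups is None:
        expr = matrix.tracks_with_role("expression")
        replicate_groups = {"expression": expr} if len(expr) > 1 else {}
    sm = filter_promoters(matrix)
    sm = median_ratio_normalize(sm)
    if replicate_groups:
        sm = average_replicates(sm, replicate_groups)
    return log_standardize(sm)


@dataclass
class PipelineResult:
    matrix: SignalMatrix
    en: dict[str, ElasticNetSelection]
    spcn: "object"
    spcn_bipartite: list[BipartiteEdge]
    network: InteractionNetwork


def run_pipeline(
    raw: SignalMatrix,
    k: int = 10,
    q_threshold: float = 0.05,
    seed: int = 0,
    replicate_groups: dict[str, list[str]] | None = None,
) -> PipelineResult:
    """Full two-arm inference from a raw-count matrix to the network."""
    sm = preprocess(raw, replicate_groups)
    en = run_elastic_net_arm(sm, k=k, seed=seed)
    spcn_net = build_spcn(sm, k=k, q_threshold=q_threshold, seed=seed)
    bipartite = extract_hm_cm_edges(spcn_net, sm.roles)
    network = intersect_arms(
        en,
        bipartite,
        provenance={
            "seed": seed,
            "k": k,
            "q_threshold": q_threshold,
            "alpha_per_hm": {hm: sel.alpha for hm, sel in en.items()},
        },
    )
    return PipelineResult(
        matrix=sm, en=en, spcn=spcn_net, spcn_bipartite=bipartite, network=network
    )
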