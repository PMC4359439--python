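"""Synthetic tumor read-count generation with known subclonal structure.

Datasets are generated from an explicit ground-truth clone tree: reference
read counts for an SSM in lineage u are drawn ``a ~ Binomial(d, zeta)`` with
``d ~ Poisson(r)`` (zero depths resampled) and ``zeta`` the expected
reference-read probability computed from the truth tree by the same
copy-number-aware accumulation the inference uses — for a diploid locus
``zeta = 1 - phi_u/2``, i.e. ``a ~ Binomial(d, 1 - phi_u + 0.5*phi_u)``.

Three designs are provided:

* linear / branching multi-population designs at the standard lineage
  proportions (:func:`table3_phis`);
* an illustrative three-population tumor (normal 25%, an SSM-only lineage B
  at 25%, and a descendant lineage C at 50% adding a homozygous deletion of
  one of B's SSM loci) whose deleted SSM has expected VAF 25% rather than
  37.5%;
* a CNV scenario: 20% normal, a 40% CNV-free lineage with 500 SSMs, and a
  descendant lineage with 200 further SSMs plus an amplification or deletion
  spanning half the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from . import vaf_model
from .genome_model import CNV, Locus, MATERNAL, PATERNAL, SSM, UNKNOWN
from .mcmc import Dataset
from .tssb import TreeState

__all__ = [
    "SimDesign",
    "GroundTruth",
    "table3_phis",
    "simulate_reads",
    "simulate_design",
    "simulate_figure4",
    "simulate_cnv_scenario",
]

#: length of the single toy contig; only overlap fractions matter
GENOME_LENGTH = 10_000_000
CHROM = "1"

#: linear-phylogeny lineage proportions by total population count (incl. normal)
_LINEAR_PHIS = {
    3: (0.44, 0.11),
    4: (0.56, 0.25, 0.06),
    5: (0.64, 0.36, 0.16, 0.04),
    6: (0.71, 0.44, 0.25, 0.11, 0.03),
}


def table3_phis(n_populations: int) -> tuple[float, ...]:
    """Cancerous lineage frequencies for the standard linear designs."""
    try:
        return _LINEAR_PHIS[n_populations]
    except KeyError:
        raise ValueError(f"no standard design for {n_populations} populations") from None


@dataclass(frozen=True)
class SimDesign:
    """Multi-population simulation design (no CNVs).

    ``phis`` are cancerous lineage frequencies, largest first; the normal
    fraction is ``1 - phis[0]``.  ``topology`` is 'linear' (a chain) or
    'branching' (the two deepest lineages become siblings).
    """

    n_populations: int = 3
    phis: Optional[tuple[float, ...]] = None
    read_depth: float = 200.0
    ssms_per_population: int = 100
    topology: Literal["linear", "branching"] = "linear"
    seed: int = 0

    def lineage_phis(self) -> tuple[float, ...]:
        phis = self.phis if self.phis is not None else table3_phis(self.n_populations)
        if any(p <= 0 or p > 1 for p in phis):
            raise ValueError("lineage frequencies must lie in (0, 1]")
        return phis


@dataclass
class GroundTruth:
    """Generating tree, mutation assignments and lineage frequencies."""

    tree: TreeState
    assignment: dict[str, int]  # mutation id -> true node id
    n_populations: int  # total, including the normal root

    def ssm_labels(self, ssm_ids: Sequence[str]) -> list[int]:
        return [self.assignment[i] for i in ssm_ids]

    def phis(self, sample: int = 0) -> dict[int, float]:
        from .tssb import phi_from_eta
        return {u.id: phi for u, phi in phi_from_eta(self.tree, sample).items()}

    def to_json_dict(self) -> dict:
        return {
            "tree": self.tree.to_dict(),
            "assignment": self.assignment,
            "n_populations": self.n_populations,
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "GroundTruth":
        return cls(tree=TreeState.from_dict(payload["tree"]),
                   assignment={k: int(v) for k, v in payload["assignment"].items()},
                   n_populations=int(payload["n_populations"]))


def simulate_reads(phi_u: float, r: float, n_ssms: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (a, d) pairs for ``n_ssms`` diploid-locus SSMs in a lineage of
    frequency ``phi_u``: d ~ Poisson(r) (zeros resampled), then
    a ~ Binomial(d, 1 - phi_u + 0.5*phi_u)."""
    if not 0.0 <= phi_u <= 1.0:
        raise ValueError("phi_u must lie in [0, 1]")
    if r <= 0:
        raise ValueError("read depth must be positive")
    d = rng.poisson(r, size=n_ssms)
    while np.any(d == 0):
        zeros = d == 0
        d[zeros] = rng.poisson(r, size=int(zeros.sum()))
    a = rng.binomial(d, 1.0 - phi_u + 0.5 * phi_u)
    return a, d


def _sample_depths(r: float, n: int, rng: np.random.Generator) -> np.ndarray:
    d = rng.poisson(r, size=n)
    while np.any(d == 0):
        zeros = d == 0
        d[zeros] = rng.poisson(r, size=int(zeros.sum()))
    return d


def _chain_tree(etas: Sequence[float]) -> TreeState:
    """Build a chain tree root -> ... with the given per-node eta masses."""
    tree = TreeState(n_samples=1)
    tree.root.eta[0] = etas[0]
    parent = tree.root
    for eta in etas[1:]:
        node = tree._new_node(parent)
        node.eta[0] = eta
        parent.children.append(node)
        parent = node
    return tree


def _truth_tree(phis: Sequence[float], topology: str) -> TreeState:
    """Truth tree for a multi-population design; node ids follow creation
    order (root=0, then lineages largest-phi first)."""
    phis = list(phis)
    if topology == "linear":
        etas = [1.0 - phis[0]]
        for i, p in enumerate(phis):
            nxt = phis[i + 1] if i + 1 < len(phis) else 0.0
            if nxt > p:
                raise ValueError("linear design needs non-increasing phis")
            etas.append(p - nxt)
        return _chain_tree(etas)
    if topology != "branching":
        raise ValueError(f"unknown topology {topology!r}")
    if len(phis) < 2:
        return _chain_tree([1.0 - phis[0], phis[0]])
    # chain down to the (k-2)-th lineage, deepest two lineages as siblings
    chain, siblings = phis[:-2], phis[-2:]
    parent_phi = chain[-1] if chain else 1.0
    if sum(siblings) > parent_phi + 1e-12:
        raise ValueError("sibling frequencies exceed their parent's")
    tree = TreeState(n_samples=1)
    tree.root.eta[0] = (1.0 - phis[0]) if chain else (1.0 - sum(siblings))
    parent = tree.root
    for i, p in enumerate(chain):
        nxt = chain[i + 1] if i + 1 < len(chain) else sum(siblings)
        node = tree._new_node(parent)
        node.eta[0] = p - nxt
        parent.children.append(node)
        parent = node
    for p in siblings:
        node = tree._new_node(parent)
        node.eta[0] = p
        parent.children.append(node)
    return tree


def _draw_ssms_for_tree(tree: TreeState, cnvs: list[CNV], cnv_node_ids: dict[str, int],
                        ssm_specs: list[tuple[str, int, Optional[Locus], str]],
                        depth: float, rng: np.random.Generator) -> list[SSM]:
    """Draw read counts for SSM specs (id, node_id, locus, phase) so that the
    expected VAF matches the copy-number-aware model on the truth tree."""
    nodes_by_id = {u.id: u for u in tree.nodes()}
    cnvs_by_id = {c.id: c for c in cnvs}
    eta_map = tree.eta_map(0)
    ssms = []
    for ssm_id, node_id, locus, phase in ssm_specs:
        overlap_nodes = {
            c.id: nodes_by_id[cnv_node_ids[c.id]]
            for c in cnvs if locus is not None and c.contains(locus)
        }
        counts = vaf_model.accumulate_locus_counts(
            tree, nodes_by_id[node_id], overlap_nodes, cnvs_by_id, eta_map,
            phase=phase if phase != UNKNOWN else MATERNAL)
        zeta = vaf_model.reference_read_probability(counts, epsilon=0.0)
        d = int(_sample_depths(depth, 1, rng)[0])
        a = int(rng.binomial(d, zeta))
        ssms.append(SSM(id=ssm_id, a=[a], d=[d], mu_r=1.0, mu_v=0.5,
                        locus=locus, phase=phase, epsilon=0.0))
    return ssms


def simulate_design(design: SimDesign,
                    rng: Optional[np.random.Generator] = None) -> tuple[Dataset, GroundTruth]:
    """Generate a CNV-free multi-population dataset from a :class:`SimDesign`."""
    if design.ssms_per_population <= 0:
        raise ValueError("ssms_per_population must be positive")
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    phis = design.lineage_phis()
    tree = _truth_tree(phis, design.topology)
    lineage_nodes = [u for u in tree.nodes() if u.parent is not None]
    from .tssb import phi_from_eta
    phi_map = phi_from_eta(tree, 0)

    ssms: list[SSM] = []
    assignment: dict[str, int] = {}
    k = 0
    for node in lineage_nodes:
        a_arr, d_arr = simulate_reads(phi_map[node], design.read_depth,
                                      design.ssms_per_population, rng)
        for a, d in zip(a_arr, d_arr):
            ssm_id = f"s{k}"
            pos = int(rng.integers(0, GENOME_LENGTH))
            ssms.append(SSM(id=ssm_id, a=[int(a)], d=[int(d)], mu_r=1.0, mu_v=0.5,
                            locus=Locus(CHROM, pos), epsilon=0.0))
            assignment[ssm_id] = node.id
            node.mutations.append(ssm_id)
            k += 1
    truth = GroundTruth(tree=tree, assignment=assignment,
                        n_populations=len(lineage_nodes) + 1)
    return Dataset.build(ssms), truth


def simulate_figure4(depth: float = 60.0,
                     rng: Optional[np.random.Generator] = None,
                     support_depth: Optional[int] = None) -> tuple[Dataset, GroundTruth]:
    """The worked-example tumor: normal A (25%), lineage B (25%, SSM1-4),
    descendant lineage C (50%, SSM5-8 plus a homozygous deletion of the
    SSM4 locus).  Expected VAFs are 37.5% for SSM1-3 and 25% for SSM4 (via
    the deletion) and SSM5-8."""
    rng = rng if rng is not None else np.random.default_rng(0)
    tree = _chain_tree([0.25, 0.25, 0.5])
    node_a, node_b, node_c = tree.nodes()

    cnv_region = (5_000_000, 6_000_000)
    cnv = CNV(id="cnv1", chrom=CHROM, start=cnv_region[0], end=cnv_region[1],
              C=0, Cm=0, Cp=0, phi=[0.5],
              support_depth=support_depth or int(round(2 * depth)))
    specs = []
    for i in range(1, 9):
        node = node_b if i <= 4 else node_c
        # SSM4 sits inside the deleted region; all others at diploid loci
        pos = (cnv_region[0] + cnv_region[1]) // 2 if i == 4 else 100_000 * i
        specs.append((f"s{i}", node.id, Locus(CHROM, pos), UNKNOWN))
    ssms = _draw_ssms_for_tree(tree, [cnv], {"cnv1": node_c.id}, specs, depth, rng)

    assignment = {f"s{i}": (node_b.id if i <= 4 else node_c.id) for i in range(1, 9)}
    assignment["cnv_cnv1"] = node_c.id
    for mid, nid in assignment.items():
        tree.find(nid).mutations.append(mid)
    truth = GroundTruth(tree=tree, assignment=assignment, n_populations=3)
    return Dataset.build(ssms, [cnv]), truth


def simulate_cnv_scenario(read_depth: float, kind: Literal["amplification", "deletion"],
                          rng: Optional[np.random.Generator] = None,
                          n_first: int = 500, n_second: int = 200
                          ) -> tuple[Dataset, GroundTruth]:
    """20% normal, a 40% CNV-free lineage with ``n_first`` SSMs, and a
    descendant lineage (40%) adding ``n_second`` SSMs plus one CNV covering
    half the genome: amplification C=3 (Cm=2, Cp=1) or deletion C=1
    (Cm=0, Cp=1).  First-lineage SSMs inside the CNV region are phased (the
    generating copy is recorded) so their expected VAF follows the
    SSM-before-CNV closed form."""
    if kind not in ("amplification", "deletion"):
        raise ValueError(f"kind must be amplification or deletion, got {kind!r}")
    rng = rng if rng is not None else np.random.default_rng(0)
    tree = _chain_tree([0.2, 0.4, 0.4])
    _, p1, p2 = tree.nodes()

    C, Cm, Cp = (3, 2, 1) if kind == "amplification" else (1, 0, 1)
    half = GENOME_LENGTH // 2
    cnv = CNV(id="cnv1", chrom=CHROM, start=0, end=half, C=C, Cm=Cm, Cp=Cp,
              phi=[0.4], support_depth=int(round(2 * read_depth)))

    specs = []
    for k in range(n_first + n_second):
        node = p1 if k < n_first else p2
        pos = int(rng.integers(0, GENOME_LENGTH))
        phase = UNKNOWN
        if node is p1 and pos < half:
            # ancestral SSM hit by the later CNV: record the copy it sits on
            phase = MATERNAL if rng.uniform() < 0.5 else PATERNAL
        specs.append((f"s{k}", node.id, Locus(CHROM, pos), phase))
    ssms = _draw_ssms_for_tree(tree, [cnv], {"cnv1": p2.id}, specs, read_depth, rng)

    assignment = {f"s{k}": (p1.id if k < n_first else p2.id)
                  for k in range(n_first + n_second)}
    assignment["cnv_cnv1"] = p2.id
    for mid, nid in assignment.items():
        tree.find(nid).mutations.append(mid)
    truth = GroundTruth(tree=tree, assignment=assignment, n_populations=3)
    return Dataset.build(ssms, [cnv]), truth
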