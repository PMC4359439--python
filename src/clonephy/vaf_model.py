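"""Copy-number-aware transformation between population frequency and VAF.

For an SSM whose locus is covered by a subclonal CNV, the expected variant
allele frequency depends on the phylogenetic relationship between the two
events.  With phi_s the SSM population frequency, phi_c the CNV population
frequency, and C = Cm + Cp the total copy number in CNV-bearing cells:

* SSM before CNV on one branch (the CNV hits a mutated locus)::

      x = (Cm*phi_c + (phi_s - phi_c)) / (2*(1 - phi_c) + C*phi_c)

* CNV before SSM, or SSM and CNV on disjoint branches::

      x = phi_s / (2*(1 - phi_c) + C*phi_c)

The general machinery evaluates these through per-population locus copy
counts: walking every tree node u with cell mass eta_u, the average number
of reference-bearing (Nr) and variant-bearing (Nv) copies per cell is
accumulated according to which of five situations holds at u — no SSM and
no CNV (diploid reference), no SSM with CNV, SSM without CNV, SSM after
CNV, SSM before CNV.  The probability that a read shows the reference
allele is then

      zeta = (Nr*(1 - eps) + Nv*eps) / (Nr + Nv)

and reference read counts are Binomial(d, zeta).  Unphased SSMs average
the maternal- and paternal-placement likelihoods.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .genome_model import CNV, MATERNAL, PATERNAL, UNKNOWN, SSM

__all__ = [
    "ConstraintError",
    "DegenerateLocusError",
    "LocusCounts",
    "PhyloRelation",
    "expected_vaf_case1",
    "expected_vaf_case2or3",
    "infer_phi_case3",
    "case1_infeasible",
    "classify_relation",
    "accumulate_locus_counts",
    "reference_read_probability",
    "ssm_log_likelihood",
    "binom_logpmf",
]


class ConstraintError(ValueError):
    """A clonal-evolution constraint (ISA / frequency ordering) is violated."""


class DegenerateLocusError(ValueError):
    """All copies of a locus are deleted in every population (Nr + Nv = 0)."""


@dataclass(frozen=True)
class LocusCounts:
    """Average copies per cell of a locus bearing the reference (Nr) and the
    variant (Nv) allele, accumulated over all populations."""

    Nr: float
    Nv: float


class PhyloRelation(enum.Enum):
    """Situation of one population relative to one SSM and its governing CNV."""

    NO_SSM_NO_CNV = 1
    NO_SSM_WITH_CNV = 2
    SSM_NO_CNV = 3
    CNV_THEN_SSM = 4  # population has the SSM; CNV occurred first (or same node)
    SSM_THEN_CNV = 5  # population has the SSM; CNV hit the mutated locus later


def _denominator(phi_c: float, C: float) -> float:
    return 2.0 * (1.0 - phi_c) + C * phi_c


def expected_vaf_case1(phi_s: float, phi_c: float, C: int, Cm: int) -> float:
    """Expected VAF when the SSM precedes the CNV on the same branch.

    Cells with the CNV carry ``Cm`` mutated copies (the SSM is taken to sit
    on the maternal copy); cells with the SSM but not the CNV carry one.
    Requires phi_s >= phi_c > 0 under the infinite sites assumption.
    """
    if not phi_s >= phi_c > 0.0:
        raise ConstraintError(f"case 1 requires phi_s >= phi_c > 0, got {phi_s}, {phi_c}")
    if Cm > C:
        raise ConstraintError(f"Cm={Cm} exceeds C={C}")
    return (Cm * phi_c + (phi_s - phi_c)) / _denominator(phi_c, C)


def expected_vaf_case2or3(phi_s: float, phi_c: float, C: int) -> float:
    """Expected VAF when the CNV precedes the SSM (case 2) or the two lie on
    disjoint branches (case 3); identical in both cases since exactly one
    copy per SSM-bearing cell is mutated."""
    if phi_s < 0 or phi_c < 0 or phi_c > 1:
        raise ConstraintError("frequencies must lie in [0, 1]")
    return phi_s / _denominator(phi_c, C)


def infer_phi_case3(x_ssm: float, phi_c: float, C: int) -> float:
    """Invert the case-2/3 relation: phi_s = x * (2*(1-phi_c) + C*phi_c).

    The result is infeasible as a branching (case 3) configuration when
    phi_s + phi_c > 1.
    """
    if not 0.0 <= x_ssm <= 1.0:
        raise ConstraintError(f"x_ssm={x_ssm} outside [0, 1]")
    return x_ssm * _denominator(phi_c, C)


def case1_infeasible(x_ssm: float, phi_c: float, C: int, Cm: int) -> bool:
    """True when no non-negative phi_s satisfies the case-1 relation, i.e.

        x_ssm * (2*(1 - phi_c) + C*phi_c) < (Cm - 1) * phi_c

    in which case a branching phylogeny (case 3) is identified unambiguously
    from a single sample."""
    return x_ssm * _denominator(phi_c, C) < (Cm - 1) * phi_c


# ---------------------------------------------------------------------------
# Five-case accumulation over a clone tree
# ---------------------------------------------------------------------------

def classify_relation(tree, ssm_node, population_node, overlap_cnv_nodes):
    """Determine which of the five situations governs ``population_node``.

    ``overlap_cnv_nodes`` maps cnv_id -> tree node for every CNV overlapping
    the SSM locus.  The governing CNV is found by ascending from the
    population toward the root; the first node carrying an overlapping CNV
    wins (ties at one node broken by the mapping's insertion order).  The
    SSM is contained in the population iff the population is the SSM's node
    or one of its descendants; event order is read off the ancestor /
    descendant relation of the two host nodes.  A CNV at the SSM's own node
    counts as CNV-then-SSM (within-node order is unobservable).

    Returns ``(PhyloRelation, governing_cnv_id or None)``.
    """
    node_to_cnvs: dict = {}
    for cnv_id, node in overlap_cnv_nodes.items():
        node_to_cnvs.setdefault(id(node), (node, []))[1].append(cnv_id)

    governing = None
    u = population_node
    while u is not None:
        if id(u) in node_to_cnvs:
            governing = node_to_cnvs[id(u)][1][0]
            break
        u = u.parent

    has_ssm = tree.is_ancestor_or_self(ssm_node, population_node)
    if governing is None:
        return (PhyloRelation.SSM_NO_CNV if has_ssm else PhyloRelation.NO_SSM_NO_CNV), None
    if not has_ssm:
        return PhyloRelation.NO_SSM_WITH_CNV, governing
    cnv_node = overlap_cnv_nodes[governing]
    if cnv_node is not ssm_node and tree.is_ancestor_or_self(ssm_node, cnv_node):
        return PhyloRelation.SSM_THEN_CNV, governing
    return PhyloRelation.CNV_THEN_SSM, governing


def accumulate_locus_counts(
    tree,
    ssm_node,
    overlap_cnv_nodes: Mapping[str, object],
    cnvs_by_id: Mapping[str, CNV],
    eta_by_node: Mapping[object, float],
    phase: str = MATERNAL,
) -> LocusCounts:
    """Accumulate Nr/Nv over every population of the tree for one SSM.

    Populations without a governing CNV are diploid (C = 2 implicitly).
    ``phase`` selects which parental copy carries the SSM for populations
    where the SSM preceded the CNV.
    """
    Nr = 0.0
    Nv = 0.0
    for node, eta in eta_by_node.items():
        rel, gov = classify_relation(tree, ssm_node, node, overlap_cnv_nodes)
        if rel is PhyloRelation.NO_SSM_NO_CNV:
            Nr += 2.0 * eta
        elif rel is PhyloRelation.NO_SSM_WITH_CNV:
            Nr += eta * cnvs_by_id[gov].C
        elif rel is PhyloRelation.SSM_NO_CNV:
            Nr += eta
            Nv += eta
        elif rel is PhyloRelation.CNV_THEN_SSM:
            cnv = cnvs_by_id[gov]
            if cnv.C < 1:
                # no surviving copy to mutate: SSM after a homozygous
                # deletion is impossible under the ISA
                raise ConstraintError(
                    f"SSM cannot arise after homozygous deletion (CNV {gov})")
            Nr += eta * max(0, cnv.C - 1)
            Nv += eta
        else:  # SSM_THEN_CNV
            cnv = cnvs_by_id[gov]
            if phase == MATERNAL:
                Nr += eta * cnv.Cp
                Nv += eta * cnv.Cm
            else:
                Nr += eta * cnv.Cm
                Nv += eta * cnv.Cp
    if Nr + Nv <= 0.0:
        raise DegenerateLocusError("locus deleted in every population (Nr + Nv = 0)")
    return LocusCounts(Nr=Nr, Nv=Nv)


def reference_read_probability(counts: LocusCounts, epsilon: float) -> float:
    """zeta = (Nr*(1-eps) + Nv*eps) / (Nr + Nv), the probability a read at
    the locus shows the reference allele."""
    total = counts.Nr + counts.Nv
    if total <= 0:
        raise DegenerateLocusError("Nr + Nv must be positive")
    return (counts.Nr * (1.0 - epsilon) + counts.Nv * epsilon) / total


def binom_logpmf(a: np.ndarray, d: np.ndarray, p) -> np.ndarray:
    """Binomial log-pmf, vectorized; tolerates p in {0, 1} at the boundary."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1.0 - 1e-16)
    return (gammaln(d + 1) - gammaln(a + 1) - gammaln(d - a + 1)
            + a * np.log(p) + (d - a) * np.log1p(-p))


def _unphased_needs_averaging(ssm: SSM, tree, ssm_node, overlap_cnv_nodes, cnvs_by_id) -> bool:
    """Averaging matters only when an SSM-then-CNV population exists with an
    asymmetric Cm/Cp breakdown."""
    if ssm.phase != UNKNOWN:
        return False
    for cnv_id, cnv_node in overlap_cnv_nodes.items():
        if cnv_node is not ssm_node and tree.is_ancestor_or_self(ssm_node, cnv_node):
            cnv = cnvs_by_id[cnv_id]
            if cnv.Cm != cnv.Cp:
                return True
    return False


def ssm_log_likelihood(
    ssm: SSM,
    tree,
    ssm_node,
    overlap_cnv_nodes: Mapping[str, object],
    cnvs_by_id: Mapping[str, CNV],
    eta_by_node_per_sample: Sequence[Mapping[object, float]],
) -> float:
    """Log-likelihood of one SSM's reference read counts over all samples.

    With no overlapping CNV this reduces to
    ``a ~ Binomial(d, (1-phi)*mu_r + phi*mu_v)`` with phi the frequency of
    the SSM's node.  With CNVs the five-case accumulation gives zeta per
    sample.  For unphased SSMs in an SSM-then-CNV configuration the
    *likelihood* (not log-likelihood) is averaged over the two parental
    placements, jointly across samples.
    """
    if not overlap_cnv_nodes:
        total = 0.0
        for s, eta_map in enumerate(eta_by_node_per_sample):
            phi = _subtree_mass(tree, ssm_node, eta_map)
            p = (1.0 - phi) * ssm.mu_r + phi * ssm.mu_v
            total += float(binom_logpmf(ssm.a[s], ssm.d[s], p))
        return total

    phases = [ssm.phase] if ssm.phase != UNKNOWN else [MATERNAL]
    if _unphased_needs_averaging(ssm, tree, ssm_node, overlap_cnv_nodes, cnvs_by_id):
        phases = [MATERNAL, PATERNAL]

    per_phase = []
    for phase in phases:
        ll = 0.0
        try:
            for s, eta_map in enumerate(eta_by_node_per_sample):
                counts = accumulate_locus_counts(
                    tree, ssm_node, overlap_cnv_nodes, cnvs_by_id, eta_map, phase=phase)
                zeta = reference_read_probability(counts, ssm.epsilon)
                ll += float(binom_logpmf(ssm.a[s], ssm.d[s], zeta))
        except ConstraintError:
            ll = -math.inf
        per_phase.append(ll)
    if all(ll == -math.inf for ll in per_phase):
        raise ConstraintError("SSM placement incompatible with overlapping CNVs")
    if len(per_phase) == 1:
        return per_phase[0]
    return float(logsumexp(per_phase) - math.log(len(per_phase)))


def _subtree_mass(tree, node, eta_map: Mapping[object, float]) -> float:
    """phi of ``node``: total eta over the node and its descendants."""
    total = eta_map.get(node, 0.0)
    for child in node.children:
        total += _subtree_mass(tree, child, eta_map)
    return total
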