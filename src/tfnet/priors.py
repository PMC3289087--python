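"""Prior regulation probabilities from database knowledge.

A regulatory database (e.g. a TRANSFAC export) is an imperfect estimate of the
true network.  Given its assumed precision ``p``, recall ``r`` and the overall
network sparsity ``s``, confusion-matrix counting yields the probability that
a recorded pair is truly regulated (``p`` itself) and the probability that an
unrecorded pair is regulated despite the database's silence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PriorNetwork", "pi_from_quality", "build_prior_network"]

#: Illustrative genome-scale default for a pair absent from the database:
#: a typical TF regulating ~500 of ~20000 genes.
DEFAULT_UNRECORDED_PI = 500 / 20000

PI_CLIP = 1e-6


@dataclass
class PriorNetwork:
    """Per-(gene, TF) prior probabilities of regulation plus the edge list."""

    genes: list[str]
    tfs: list[str]
    edges: set[tuple[str, str]]
    pi: np.ndarray  # G x L, entries in [0, 1]

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (len(self.genes), len(self.tfs)):
            raise ValueError(
                f"pi shape {self.pi.shape} does not match "
                f"{len(self.genes)} genes x {len(self.tfs)} TFs"
            )
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("pi entries must lie in [0, 1]")
        known = set(self.genes), set(self.tfs)
        for g, t in self.edges:
            if g not in known[0] or t not in known[1]:
                raise ValueError(f"edge ({g}, {t}) references unknown labels")

    def clamped_pi(self, clip: float = PI_CLIP) -> np.ndarray:
        """pi pushed off exact 0/1 to avoid absorbing sampler states.

        Entries that are *exactly* 0 or 1 are treated as hard constraints by
        the sampler and are left untouched here only when ``clip`` is 0.
        """
        return np.clip(self.pi, clip, 1.0 - clip)


def pi_from_quality(
    precision: float, recall: float, sparsity: float
) -> tuple[float, float]:
    """Prior regulation probabilities implied by database quality.

    In a universe of ``M`` gene-TF pairs with ``s*M`` true edges, a database
    with recall ``r`` records ``r*s*M`` of them, and with precision ``p`` it
    contains ``r*s*M/p`` entries in total.  Counting true edges on each side
    of the database gives

        P(edge | recorded)   = p
        P(edge | unrecorded) = s(1-r) / (1 - s*r/p)
    """
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    if not 0 < sparsity < 1:
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    denom = 1.0 - sparsity * recall / precision
    if denom <= 0:
        raise ValueError(
            "infeasible quality: database would cover the whole pair universe"
        )
    pi_unrecorded = sparsity * (1.0 - recall) / denom
    return precision, pi_unrecorded


def build_prior_network(
    genes,
    tfs,
    edges,
    pi_recorded: float = 0.9,
    pi_unrecorded: float = DEFAULT_UNRECORDED_PI,
) -> PriorNetwork:
    """Expand an edge list into the dense G x L matrix of prior probabilities.

    A noninformative baseline is obtained with
    ``pi_recorded = pi_unrecorded = 0.5``.
    """
    genes = list(genes)
    tfs = list(tfs)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene labels")
    if len(set(tfs)) != len(tfs):
        raise ValueError("duplicate TF labels")
    for name, v in (("pi_recorded", pi_recorded), ("pi_unrecorded", pi_unrecorded)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    edges = set(tuple(e) for e in edges)
    gene_idx = {g: i for i, g in enumerate(genes)}
    tf_idx = {t: j for j, t in enumerate(tfs)}
    pi = np.full((len(genes), len(tfs)), pi_unrecorded, dtype=float)
    for g, t in edges:
        if g not in gene_idx or t not in tf_idx:
            raise ValueError(f"edge ({g}, {t}) references unknown labels")
        pi[gene_idx[g], tf_idx[t]] = pi_recorded
    return PriorNetwork(genes=genes, tfs=tfs, edges=edges, pi=pi)
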