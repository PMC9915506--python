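"""Select the single orthology-confident chain per species and gene.

Downstream gap and conservation calls only trust chains that confidently
carry the ortholog of a reference gene.  Confidence is expressed as two
inclusive ratio criteria with a common default threshold of 10:

* second-best-chain ratio: aligned reference bases inside the gene span of
  the best chain must be at least 10x those of the runner-up chain
  (vacuously satisfied when no other chain touches the gene);
* gene-in-synteny ratio: the winning chain's genome-wide aligned bases must
  be at least 10x its in-gene aligned bases, i.e. the chain must carry
  substantial syntenic context beyond the gene itself.

Both are computable from chain files alone.  This is an explicit,
configurable interpretation of an orthology-mapping contract whose original
implementation lives in prior work; it is isolated behind
:func:`map_gene_to_chain`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chain import Chain
from .genes import GeneModel
from .intervals import Interval

__all__ = ["OrthologyCall", "aligned_bases_in_span", "map_gene_to_chain"]


@dataclass(frozen=True)
class OrthologyCall:
    species_id: str
    gene_id: str
    chain_id: int
    in_gene_aligned: int
    second_in_gene_aligned: int
    total_aligned: int

    @property
    def ratio_second(self) -> float:
        return self.in_gene_aligned / max(self.second_in_gene_aligned, 1)

    @property
    def ratio_synteny(self) -> float:
        return self.total_aligned / max(self.in_gene_aligned, 1)


def aligned_bases_in_span(chain: Chain, span: Interval) -> int:
    """Aligned reference bases of ``chain`` falling inside ``span``.

    A chrom mismatch yields 0 (the chain simply does not map the gene's
    chromosome); it is not an error.
    """
    if chain.t_name != span.chrom:
        return 0
    total = 0
    for bs, be in chain.ref_blocks():
        lo = max(bs, span.start)
        hi = min(be, span.end)
        if hi > lo:
            total += hi - lo
        if bs >= span.end:
            break
    return total


def map_gene_to_chain(
    gene: GeneModel,
    chains_of_species: Sequence[Chain],
    species_id: str = "",
    ratio_threshold: float = 10.0,
    synteny_threshold: float = 10.0,
) -> OrthologyCall | None:
    """Pick the orthologous chain for one gene, or None if no chain qualifies.

    Candidates are chains with any aligned base in the gene span; the
    winner has the most (ties: higher chain score, then smaller chain id).
    The call is returned iff both ratio criteria meet their thresholds
    (inclusively).  Deterministic and independent of input chain order.
    """
    span = gene.span
    scored = []
    for chain in chains_of_species:
        n = aligned_bases_in_span(chain, span)
        if n > 0:
            scored.append((n, chain.score, -chain.chain_id, chain))
    if not scored:
        return None
    scored.sort(reverse=True)
    in_gene, _, _, winner = scored[0]
    second = scored[1][0] if len(scored) > 1 else 0
    call = OrthologyCall(
        species_id=species_id,
        gene_id=gene.gene_id,
        chain_id=winner.chain_id,
        in_gene_aligned=in_gene,
        second_in_gene_aligned=second,
        total_aligned=winner.aligned_bases(),
    )
    if call.ratio_second >= ratio_threshold \
            and call.ratio_synteny >= synteny_threshold:
        return call
    return None
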