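"""UCSC chain format: parsing, writing, and coordinate conventions.

A chain records one pairwise alignment between a query genome and the
reference as an ordered list of ungapped blocks separated by reference-side
(``dt``) and query-side (``dq``) gap lengths.  The reference ("target")
strand is always '+'; query coordinates are given on the stated query
strand, so minus-strand coordinates must be reflected before they can be
compared with anything computed on the query's plus strand (e.g. assembly
gap N-runs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

__all__ = [
    "Chain",
    "ChainParseError",
    "parse_chain_text",
    "parse_chain_file",
    "write_chain_text",
    "write_chain_file",
    "query_interval_on_plus",
]


class ChainParseError(ValueError):
    """Malformed chain text; message includes the 1-based line number."""


@dataclass(frozen=True)
class Chain:
    """One pairwise alignment chain.

    ``blocks`` is a sequence of ``(size, dt, dq)`` triples: ``size`` aligned
    bases followed by a gap of ``dt`` reference bases and ``dq`` query
    bases.  The final block always has ``dt = dq = 0``.
    """

    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.t_strand != "+":
            raise ValueError("reference strand must be '+'")
        if self.q_strand not in "+-":
            raise ValueError(f"bad query strand {self.q_strand!r}")
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise ValueError("reference span outside [0, t_size]")
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ValueError("query span outside [0, q_size]")
        if not self.blocks:
            raise ValueError("chain needs at least one block")
        t_span = sum(s + dt for s, dt, _ in self.blocks)
        q_span = sum(s + dq for s, _, dq in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"block sum {t_span} != reference span "
                f"{self.t_end - self.t_start}")
        if q_span != self.q_end - self.q_start:
            raise ValueError(
                f"block sum {q_span} != query span {self.q_end - self.q_start}")
        last = len(self.blocks) - 1
        for i, (size, dt, dq) in enumerate(self.blocks):
            if size <= 0 or dt < 0 or dq < 0:
                raise ValueError(f"block {i}: need size > 0 and dt, dq >= 0")
            if i == last and (dt or dq):
                raise ValueError("final block must have dt = dq = 0")
            if i != last and dt == 0 and dq == 0:
                raise ValueError(f"block {i}: empty separator (dt = dq = 0)")

    # -- derived geometry ----------------------------------------------------

    def ref_blocks(self) -> Iterator[tuple[int, int]]:
        """Reference coordinates ``(start, end)`` of each ungapped block."""
        t = self.t_start
        for size, dt, _ in self.blocks:
            yield t, t + size
            t += size + dt

    def block_coords(self) -> Iterator[tuple[int, int, int, int]]:
        """Per block: (t_start, t_end, q_start, q_end), q on stated strand."""
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            yield t, t + size, q, q + size
            t += size + dt
            q += size + dq

    def aligned_bases(self) -> int:
        return sum(size for size, _, _ in self.blocks)


def parse_chain_text(text: str) -> list[Chain]:
    """Parse chain-format text into :class:`Chain` records, order preserved."""
    chains: list[Chain] = []
    header: list[str] | None = None
    header_line = 0
    blocks: list[tuple[int, int, int]] = []

    def finish(lineno: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] or blocks[-1][2]:
            raise ChainParseError(
                f"line {lineno}: chain starting at line {header_line} "
                "not terminated by a bare size line")
        try:
            chains.append(Chain(
                score=int(header[1]),
                t_name=header[2], t_size=int(header[3]),
                t_strand=header[4],
                t_start=int(header[5]), t_end=int(header[6]),
                q_name=header[7], q_size=int(header[8]),
                q_strand=header[9],
                q_start=int(header[10]), q_end=int(header[11]),
                chain_id=int(header[12]),
                blocks=tuple(blocks),
            ))
        except ValueError as exc:
            raise ChainParseError(
                f"line {header_line}: {exc}") from exc
        header, blocks = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "chain":
            finish(lineno)
            if len(fields) != 13:
                raise ChainParseError(
                    f"line {lineno}: chain header has {len(fields)} fields, "
                    "expected 13")
            header = fields
            header_line = lineno
        else:
            if header is None:
                raise ChainParseError(
                    f"line {lineno}: alignment data before any chain header")
            try:
                nums = [int(f) for f in fields]
            except ValueError:
                raise ChainParseError(
                    f"line {lineno}: non-integer block field") from None
            if len(nums) == 3:
                blocks.append((nums[0], nums[1], nums[2]))
            elif len(nums) == 1:
                blocks.append((nums[0], 0, 0))
            else:
                raise ChainParseError(
                    f"line {lineno}: block line has {len(nums)} fields, "
                    "expected 3 or 1")
            if any(n < 0 for n in nums):
                raise ChainParseError(f"line {lineno}: negative block field")
    finish(lineno if text.strip() else 0)
    return chains


def parse_chain_file(path) -> list[Chain]:
    with open(path, encoding="ascii") as fh:
        return parse_chain_text(fh.read())


def write_chain_text(chains: Sequence[Chain]) -> str:
    """Canonical chain text: header, block lines, one blank separator line."""
    out: list[str] = []
    for c in chains:
        out.append(
            f"chain {c.score} {c.t_name} {c.t_size} {c.t_strand} "
            f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
            f"{c.q_start} {c.q_end} {c.chain_id}")
        for size, dt, dq in c.blocks[:-1]:
            out.append(f"{size} {dt} {dq}")
        out.append(str(c.blocks[-1][0]))
        out.append("")
    return "\n".join(out) + ("\n" if out else "")


def write_chain_file(path, chains: Sequence[Chain]) -> None:
    with open(path, "w", encoding="ascii") as fh:
        fh.write(write_chain_text(chains))


def query_interval_on_plus(chain: Chain, q_local_start: int,
                           q_local_end: int) -> tuple[int, int]:
    """Map a query interval from the chain's stated strand to the plus strand.

    ``[start, end)`` on the minus strand reflects to
    ``[q_size - end, q_size - start)``.  Returns a bare ``(start, end)``
    pair because zero-length points are legal here: a single-sided gap
    (``dq = 0``) has a point-like query context.
    """
    if not (0 <= q_local_start <= q_local_end <= chain.q_size):
        raise ValueError(
            f"query interval [{q_local_start},{q_local_end}) outside "
            f"[0, {chain.q_size}]")
    if chain.q_strand == "+":
        return q_local_start, q_local_end
    return chain.q_size - q_local_end, chain.q_size - q_local_start
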