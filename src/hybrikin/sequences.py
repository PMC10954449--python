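"""Sequence and duplex representations for annealing-kinetics studies.

Oligonucleotides are plain 5'->3' base strings (DNA or RNA) optionally
carrying 2-aminopurine (2Ap) markers, a fluorescent adenine analogue that
pairs like A. Duplexes are described *constructively*: a probe strand, a
partner strand, and an explicit list of declared defects (mismatches or
bulges) at 1-based probe positions counted 5'->3'. No alignment search is
performed -- the declared defects define the antiparallel register, and the
annotation step only verifies that the sequences are consistent with it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"

_DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

Alphabet = Literal["DNA", "RNA"]


class SequenceError(ValueError):
    """Raised for malformed sequences, defects, or duplex annotations."""


@dataclass(frozen=True)
class Sequence:
    """A 5'->3' nucleotide string with alphabet and optional 2Ap markers.

    ``ap2_positions`` are 1-based indices whose base reads as A but carries
    the 2-aminopurine fluorophore (destabilizing in DNA, neutral in RNA).
    """

    bases: str
    alphabet: Alphabet = "DNA"
    ap2_positions: frozenset[int] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceError("empty sequence")
        legal = DNA_BASES if self.alphabet == "DNA" else RNA_BASES
        for pos, base in enumerate(self.bases, start=1):
            if base not in legal:
                raise SequenceError(
                    f"illegal character {base!r} at position {pos} "
                    f"for alphabet {self.alphabet}"
                )
        object.__setattr__(self, "ap2_positions", frozenset(self.ap2_positions))
        for pos in self.ap2_positions:
            if not 1 <= pos <= len(self.bases):
                raise SequenceError(f"2Ap position {pos} outside [1, {len(self.bases)}]")
            if self.bases[pos - 1] != "A":
                raise SequenceError(
                    f"2Ap position {pos} sits on {self.bases[pos - 1]!r}, expected 'A'"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        """1-based base access."""
        return self.bases[pos - 1]

    def marked(self, marker: str = "2") -> str:
        """Base string with 2Ap positions written as the marker character."""
        chars = list(self.bases)
        for pos in self.ap2_positions:
            chars[pos - 1] = marker
        return "".join(chars)

    def to_rna(self) -> "Sequence":
        """RNA twin: T -> U, alphabet switched, markers preserved."""
        return Sequence(self.bases.replace("T", "U"), "RNA", self.ap2_positions, self.name)

    def to_dna(self) -> "Sequence":
        return Sequence(self.bases.replace("U", "T"), "DNA", self.ap2_positions, self.name)


@dataclass(frozen=True)
class DefectSpec:
    """One declared duplex defect at a 1-based probe position (5'->3').

    A mismatch replaces the partner base opposite ``probe_position`` with a
    non-complementary one; a bulge deletes it, leaving the probe base
    unpaired between two flanking pairs.
    """

    kind: Literal["mismatch", "bulge"]
    probe_position: int
    substituted_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("mismatch", "bulge"):
            raise SequenceError(f"unknown defect kind {self.kind!r}")
        if self.kind == "bulge" and self.substituted_base is not None:
            raise SequenceError("bulge specs carry no substituted_base")


@dataclass(frozen=True)
class DuplexSpec:
    """An annotated antiparallel duplex.

    ``alignment`` lists paired 1-based index couples ``(i, j)`` -- ``i`` on
    ``strand_a``, ``j`` on ``strand_b`` (the probe) -- ordered by ascending
    probe index ``j`` (hence descending ``i``). Probe positions declared as
    bulges appear in no couple.
    """

    strand_a: Sequence
    strand_b: Sequence
    defects: tuple[DefectSpec, ...] = ()
    alignment: tuple[tuple[int, int], ...] = ()

    @property
    def mismatch_positions(self) -> frozenset[int]:
        return frozenset(d.probe_position for d in self.defects if d.kind == "mismatch")

    @property
    def bulge_positions(self) -> frozenset[int]:
        return frozenset(d.probe_position for d in self.defects if d.kind == "bulge")

    def n_pairs(self) -> int:
        return len(self.alignment)


def complement(base: str, alphabet: Alphabet = "DNA") -> str:
    table = _DNA_COMPLEMENT if alphabet == "DNA" else _RNA_COMPLEMENT
    try:
        return table[base]
    except KeyError:
        raise SequenceError(f"illegal base {base!r} for alphabet {alphabet}") from None


def is_complementary(a: str, b: str, alphabet: Alphabet = "DNA", wobble: bool = False) -> bool:
    """Watson-Crick pairing test (A-T, A-U, G-C); G-U wobble optional.

    Wobble defaults off: this package treats wobble pairs as defects.
    """
    legal = DNA_BASES if alphabet == "DNA" else RNA_BASES
    for base in (a, b):
        if base not in legal:
            raise SequenceError(f"illegal base {base!r} for alphabet {alphabet}")
    if complement(a, alphabet) == b:
        return True
    if wobble and alphabet == "RNA" and {a, b} == {"G", "U"}:
        return True
    return False


def reverse_complement(seq: Sequence) -> Sequence:
    bases = "".join(complement(b, seq.alphabet) for b in reversed(seq.bases))
    return Sequence(bases, seq.alphabet, name=f"rc_{seq.name}" if seq.name else "")


def parse_sequence(
    text: str,
    alphabet: Alphabet = "DNA",
    ap2_marker: Optional[str] = "2",
    name: str = "",
) -> Sequence:
    """Parse a raw base string; the 2Ap marker character reads as A.

    >>> parse_sequence("TGGTG2TGCGTG").ap2_positions
    frozenset({6})
    """
    stripped = "".join(text.split()).upper()
    if not stripped:
        raise SequenceError("empty input")
    ap2 = set()
    chars = []
    for pos, char in enumerate(stripped, start=1):
        if ap2_marker is not None and char == ap2_marker:
            ap2.add(pos)
            chars.append("A")
        else:
            chars.append(char)
    return Sequence("".join(chars), alphabet, frozenset(ap2), name)


def _self_nucleation_score(bases: str, alphabet: Alphabet, n: int = 3) -> int:
    """Count antiparallel self-complementary n-windows (greedy design score).

    Used to pick mismatch substitutions that minimize self-structure: the
    score is the number of window pairs (i, j) whose n-mers are mutual
    reverse complements, a proxy for hairpin/self-dimer nucleation capacity.
    """
    comp = _DNA_COMPLEMENT if alphabet == "DNA" else _RNA_COMPLEMENT
    windows = [bases[i : i + n] for i in range(len(bases) - n + 1)]
    score = 0
    for w1, w2 in itertools.combinations_with_replacement(windows, 2):
        if all(comp[a] == b for a, b in zip(w1, reversed(w2))):
            score += 1
    return score


def make_variant(
    target: Sequence,
    probe: Sequence,
    defects: Iterable[DefectSpec],
    seed: int = 0,
) -> Sequence:
    """Edit a fully complementary target into a defect-bearing competitor.

    Mismatches substitute the target base opposite the stated probe position
    with a non-complementary base (the supplied one, else a deterministic
    greedy choice minimizing the self-nucleation score, ties broken
    alphabetically after a seed-derived rotation); bulges delete it. Names
    follow the m_/b_ convention, e.g. ``m_4,9`` or ``b_4``.
    """
    defects = tuple(defects)
    if target.alphabet != probe.alphabet:
        raise SequenceError("target and probe alphabets differ")
    if len(target) != len(probe):
        raise SequenceError("target and probe lengths differ")
    rc = reverse_complement(probe)
    if target.bases != rc.bases:
        raise SequenceError("target is not fully complementary to probe")
    length = len(probe)
    positions = [d.probe_position for d in defects]
    if len(set(positions)) != len(positions):
        raise SequenceError("duplicate defect positions")
    for d in defects:
        if not 1 <= d.probe_position <= length:
            raise SequenceError(f"defect position {d.probe_position} outside [1, {length}]")
        if d.kind == "bulge" and d.probe_position in (1, length):
            raise SequenceError("terminal bulge is an overhang, not a bulge")

    chars = list(target.bases)
    # mismatches first (indices stable), then deletions from the 3' end down
    for d in defects:
        if d.kind != "mismatch":
            continue
        t_idx = length - d.probe_position + 1  # antiparallel partner index on target
        probe_base = probe.base(d.probe_position)
        if d.substituted_base is not None:
            sub = d.substituted_base.upper()
            if is_complementary(probe_base, sub, probe.alphabet):
                raise SequenceError(
                    f"substituted base {sub!r} is complementary to probe "
                    f"position {d.probe_position}"
                )
            chars[t_idx - 1] = sub
        else:
            legal = DNA_BASES if target.alphabet == "DNA" else RNA_BASES
            candidates = [b for b in legal if not is_complementary(probe_base, b, probe.alphabet)]
            rot = seed % len(candidates)
            candidates = candidates[rot:] + candidates[:rot]
            best = min(
                candidates,
                key=lambda b: (
                    _self_nucleation_score(
                        "".join(chars[: t_idx - 1]) + b + "".join(chars[t_idx:]),
                        target.alphabet,
                    ),
                    b,
                ),
            )
            chars[t_idx - 1] = best
    bulge_targets = sorted(
        (length - d.probe_position + 1 for d in defects if d.kind == "bulge"), reverse=True
    )
    for t_idx in bulge_targets:
        del chars[t_idx - 1]

    mm = sorted(d.probe_position for d in defects if d.kind == "mismatch")
    bu = sorted(d.probe_position for d in defects if d.kind == "bulge")
    parts = []
    if mm:
        parts.append("m_" + ",".join(str(p) for p in mm))
    if bu:
        parts.append("b_" + ",".join(str(p) for p in bu))
    name = "_".join(parts) if parts else target.name
    return Sequence("".join(chars), target.alphabet, name=name)


def annotate_duplex(
    strand_a: Sequence,
    strand_b: Sequence,
    defects: Iterable[DefectSpec] = (),
) -> DuplexSpec:
    """Build and verify the antiparallel alignment implied by declared defects.

    ``strand_b`` is the probe; defect positions refer to it. Defects are
    declared, never inferred: the function checks that every declared
    mismatch is indeed non-complementary, every other pair complementary,
    and every bulge interior.
    """
    defects = tuple(defects)
    if strand_a.alphabet != strand_b.alphabet:
        raise SequenceError("strand alphabets differ")
    L_b = len(strand_b)
    positions = [d.probe_position for d in defects]
    if len(set(positions)) != len(positions):
        raise SequenceError("duplicate defect positions")
    for d in defects:
        if not 1 <= d.probe_position <= L_b:
            raise SequenceError(f"defect position {d.probe_position} outside [1, {L_b}]")
    bulges = {d.probe_position for d in defects if d.kind == "bulge"}
    mismatches = {d.probe_position for d in defects if d.kind == "mismatch"}
    for p in bulges:
        if p in (1, L_b):
            raise SequenceError(f"bulge at terminal probe position {p} is not flanked by pairs")
        if p - 1 in bulges:
            raise SequenceError("adjacent bulges are not supported")
    if len(strand_a) != L_b - len(bulges):
        raise SequenceError(
            f"length mismatch: strand_a has {len(strand_a)} nt, expected "
            f"{L_b - len(bulges)} ({L_b} probe nt minus {len(bulges)} bulges)"
        )

    pairs: list[tuple[int, int]] = []
    i = len(strand_a)
    for j in range(1, L_b + 1):
        if j in bulges:
            continue
        pairs.append((i, j))
        i -= 1
    for (i, j) in pairs:
        comp = is_complementary(strand_a.base(i), strand_b.base(j), strand_a.alphabet)
        if j in mismatches and comp:
            raise SequenceError(
                f"declared mismatch at probe position {j} is actually complementary"
            )
        if j not in mismatches and not comp:
            raise SequenceError(
                f"unexpected non-complementary pair at probe position {j} "
                f"({strand_a.base(i)}-{strand_b.base(j)}); declare it as a defect"
            )
    return DuplexSpec(strand_a, strand_b, defects, tuple(pairs))


def read_fasta(path, alphabet: Alphabet = "DNA", ap2_marker: Optional[str] = "2") -> list[Sequence]:
    """Read sequences from FASTA; the 2Ap marker character is honored."""
    out = []
    for idx, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        try:
            out.append(parse_sequence(str(record.seq), alphabet, ap2_marker, name=record.id))
        except SequenceError as exc:
            raise SequenceError(f"record {idx} ({record.id!r}): {exc}") from exc
    if not out:
        raise SequenceError(f"no FASTA records found in {path}")
    return out


def write_fasta(sequences: Iterable[Sequence], path, ap2_marker: str = "2") -> None:
    records = [
        SeqRecord(Seq(s.marked(ap2_marker)), id=s.name or f"seq{k}", description="")
        for k, s in enumerate(sequences, start=1)
    ]
    SeqIO.write(records, str(path), "fasta")


def defect_class(duplex: DuplexSpec) -> str:
    """Kinetic defect class: perfect / single_mismatch / double_mismatch / bulge.

    Duplexes mixing bulges and mismatches take the mismatch class (mismatches
    dominate the zippering penalty; the experimental panel has no mixed designs).
    """
    n_mm = len(duplex.mismatch_positions)
    n_bu = len(duplex.bulge_positions)
    if n_mm == 0 and n_bu == 0:
        return "perfect"
    if n_mm == 0:
        return "bulge"
    if n_mm == 1:
        return "single_mismatch"
    return "double_mismatch"
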