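"""Sequence I/O, derived alphabets and numeric encodings.

DNA is handled on a single strand (the complementary strand is fully
determined by base pairing, so all statistics are computed on the given
5'-to-3' chain).  Two derived representations are central to everything
downstream:

* the strong/weak (S/W) alphabet, where G and C (three hydrogen bonds)
  become ``S`` and A and T (two bonds) become ``W``;
* the bond-enthalpy track, which replaces each base pair by its bond
  enthalpy, -11.8 kcal/mol for A:T and -23.8 kcal/mol for G:C.

Sequences are stored as compact ``uint8`` code arrays so that genome-scale
inputs (megabases) stay cheap to slice, count and permute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical nucleotide alphabet; code i corresponds to ALPHA_DNA[i].
ALPHA_DNA = "ACGT"
#: Strong/weak base-pair alphabet (S = G:C, W = A:T).
ALPHA_SW = "SW"

#: Bond enthalpies in kcal/mol for the two base-pair classes.
ENTHALPY_AT = -11.8
ENTHALPY_GC = -23.8

AmbiguityPolicy = Literal["drop", "strict"]


def _code_lut(alphabet: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
        lut[ord(ch.lower())] = i
    return lut


_LUT_DNA = _code_lut(ALPHA_DNA)
_LUT_SW = _code_lut(ALPHA_SW)


@dataclass
class SymbolicSequence:
    """A symbolic sequence over a small alphabet, stored as integer codes.

    Parameters
    ----------
    codes
        ``uint8`` array; ``codes[i]`` indexes into ``alphabet``.
    alphabet
        The ordered symbol set, ``"ACGT"`` for DNA or ``"SW"`` for the
        strong/weak base-pair classes.
    identifier
        Free-text record name (FASTA header).
    """

    codes: np.ndarray
    alphabet: str = ALPHA_DNA
    identifier: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.size and int(self.codes.max(initial=0)) >= len(self.alphabet):
            raise ValueError("code out of range for alphabet %r" % self.alphabet)

    @classmethod
    def from_string(
        cls, s: str, alphabet: str = ALPHA_DNA, identifier: str = ""
    ) -> "SymbolicSequence":
        lut = _LUT_DNA if alphabet == ALPHA_DNA else _code_lut(alphabet)
        raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        codes = lut[raw]
        if (codes == 255).any():
            bad = chr(int(raw[codes == 255][0]))
            raise ValueError(f"symbol {bad!r} not in alphabet {alphabet!r}")
        return cls(codes, alphabet, identifier)

    def __len__(self) -> int:
        return int(self.codes.size)

    def __str__(self) -> str:
        chars = np.frombuffer(self.alphabet.encode("ascii"), dtype=np.uint8)
        return chars[self.codes].tobytes().decode("ascii")

    def symbol_counts(self) -> dict[str, int]:
        counts = np.bincount(self.codes, minlength=len(self.alphabet))
        return {ch: int(c) for ch, c in zip(self.alphabet, counts)}

    def gc_content(self) -> float:
        """Fraction of strongly bonded (G:C / S) positions."""
        if len(self) == 0:
            raise ValueError("empty sequence")
        if self.alphabet == ALPHA_DNA:
            n_s = int(np.count_nonzero((self.codes == 1) | (self.codes == 2)))
        elif self.alphabet == ALPHA_SW:
            n_s = int(np.count_nonzero(self.codes == 0))
        else:
            raise ValueError(f"unsupported alphabet {self.alphabet!r}")
        return n_s / len(self)


@dataclass
class NumericTrack:
    """A per-position numeric series derived from a sequence."""

    values: np.ndarray
    encoding_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return int(self.values.size)


def sanitize(
    raw: str, policy: AmbiguityPolicy = "drop", identifier: str = ""
) -> SymbolicSequence:
    """Uppercase a raw nucleotide string and apply the ambiguity policy.

    ``drop`` removes positions carrying IUPAC ambiguity codes (N, R, Y, ...)
    and logs how many were removed; ``strict`` raises on the first one.
    """
    raw_bytes = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
    codes = _LUT_DNA[raw_bytes]
    bad = codes == 255
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        if policy == "strict":
            ch = chr(int(raw_bytes[bad][0]))
            raise ValueError(
                f"ambiguous/invalid symbol {ch!r} in record {identifier!r} "
                "(strict ambiguity policy)"
            )
        logger.info(
            "dropped %d ambiguous position(s) from record %r", n_bad, identifier
        )
        codes = codes[~bad]
    return SymbolicSequence(codes, ALPHA_DNA, identifier)


def read_fasta(
    path: str | Path, policy: AmbiguityPolicy = "drop"
) -> list[SymbolicSequence]:
    """Read a (multi-record) FASTA file into sanitized DNA sequences.

    Raises
    ------
    ValueError
        If the file is empty, or if content precedes the first header
        (the offending line number is reported).
    """
    path = Path(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {line_no}: expected FASTA header '>', "
                    f"got {stripped[:20]!r}"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [sanitize(str(r.seq), policy, r.id) for r in records]


def write_fasta(
    seqs: Iterable[SymbolicSequence], path: str | Path, width: int = 70
) -> None:
    records = [
        SeqRecord(Seq(str(s)), id=s.identifier or f"seq{i}", description="")
        for i, s in enumerate(seqs, start=1)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# S/W class of each ACGT code: A=0->W(1), C=1->S(0), G=2->S(0), T=3->W(1)
_SW_OF_DNA = np.array([1, 0, 0, 1], dtype=np.uint8)


def to_sw(seq: SymbolicSequence) -> SymbolicSequence:
    """Map a DNA sequence onto the strong/weak base-pair alphabet.

    A and T become ``W`` (weakly bonded), G and C become ``S`` (strongly
    bonded); length is preserved.
    """
    if seq.alphabet == ALPHA_SW:
        return seq
    if seq.alphabet != ALPHA_DNA:
        raise ValueError(f"cannot map alphabet {seq.alphabet!r} to S/W")
    return SymbolicSequence(_SW_OF_DNA[seq.codes], ALPHA_SW, seq.identifier)


def encode_enthalpy(seq: SymbolicSequence) -> NumericTrack:
    """Replace each base pair by its bond enthalpy (kcal/mol).

    A:T pairs map to -11.8, G:C pairs to -23.8; the value depends only on
    the strong/weak class of the position.
    """
    if seq.alphabet == ALPHA_DNA:
        table = np.array([ENTHALPY_AT, ENTHALPY_GC, ENTHALPY_GC, ENTHALPY_AT])
    elif seq.alphabet == ALPHA_SW:
        table = np.array([ENTHALPY_GC, ENTHALPY_AT])
    else:
        raise ValueError(f"unsupported alphabet {seq.alphabet!r}")
    return NumericTrack(table[seq.codes], "enthalpy")


def encode_indicator(seq: SymbolicSequence, target: str) -> NumericTrack:
    """0/1 indicator track for one symbol class (e.g. ``"S"`` or ``"A"``)."""
    from .intervals import class_mask  # local import to avoid cycle

    mask = class_mask(seq, target)
    return NumericTrack(mask.astype(np.float64), f"indicator:{target}")


def shuffle(seq: SymbolicSequence, seed: int) -> SymbolicSequence:
    """Uniform random permutation of the symbols (seeded, reproducible).

    Destroys all positional structure while preserving the symbol multiset,
    hence the global GC content, exactly.
    """
    rng = np.random.default_rng(seed)
    return SymbolicSequence(
        rng.permutation(seq.codes), seq.alphabet, seq.identifier
    )
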