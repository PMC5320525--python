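"""Translation, randomized reverse translation and guided codon choice.

The genetic code maps 61 sense codons onto 20 amino acids, a roughly
three-fold redundancy.  Reverse translation therefore has freedom in the
codon choice, and that freedom is where DNA-architecture information
lives:

* ``back_and_forth_test`` translates a sequence to protein and
  reverse-translates with uniformly random synonymous codons.  The protein
  is preserved exactly, but the segment-scale composition fluctuations and
  their long-range correlations are destroyed, which is visible as a drop
  of the large-scale DFA exponent toward 0.5 and a narrowing of the
  per-segment count distribution.
* ``reverse_translate_guided`` instead picks, residue by residue, the
  synonymous codon whose running within-segment strong/weak fraction has
  the minimum squared displacement from a per-segment target (e.g. an
  extrapolation of the host genome's local composition), with
  purine/pyrimidine targets breaking ties — producing synthetic DNA that
  follows the host's local nucleotide-arrangement laws.

The standard genetic code is used (identical to the bacterial table on
the 61 sense codons); in-frame stops are kept as ``*`` markers and
re-encoded as stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .dfa import estimate_hurst, fluctuation_function
from .segments import DEFAULT_SEGMENT_LENGTH, SegmentProfile, segment_counts, segment_stats
from .seqio import ALPHA_DNA, SymbolicSequence, encode_enthalpy

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard code

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _codon_index(codon: str) -> int:
    a, b, c = (_CODE[x] for x in codon)
    return a * 16 + b * 4 + c


#: amino acid (or '*') for each of the 64 codon indices
_AA_OF_CODON = np.array(["?"] * 64)
for _codon, _aa in _TABLE.forward_table.items():
    _AA_OF_CODON[_codon_index(_codon)] = _aa
for _codon in _TABLE.stop_codons:
    _AA_OF_CODON[_codon_index(_codon)] = "*"

#: synonymous codons per residue, sorted for deterministic enumeration
CODONS_OF_AA: dict[str, list[str]] = {}
for _codon in sorted(_TABLE.forward_table):
    CODONS_OF_AA.setdefault(_TABLE.forward_table[_codon], []).append(_codon)
CODONS_OF_AA["*"] = sorted(_TABLE.stop_codons)

_VALID_AA = frozenset(CODONS_OF_AA)


@dataclass
class ProteinSequence:
    residues: str
    identifier: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - _VALID_AA
        if bad:
            raise ValueError(f"invalid residue(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SegmentTargets:
    """Per-design-segment composition targets for guided reverse translation.

    ``xi_s`` is the target strong (G+C) fraction of each 150 bp segment;
    ``a_of_w`` and ``g_of_s`` are the target A-among-weak and
    G-among-strong fractions used to resolve synonymous ties.
    """

    xi_s: np.ndarray
    a_of_w: np.ndarray
    g_of_s: np.ndarray
    segment_length: int = DEFAULT_SEGMENT_LENGTH

    def __post_init__(self) -> None:
        for arr in (self.xi_s, self.a_of_w, self.g_of_s):
            a = np.asarray(arr, dtype=np.float64)
            if ((a < 0) | (a > 1)).any():
                raise ValueError("targets must lie in [0, 1]")

    def __len__(self) -> int:
        return int(np.asarray(self.xi_s).size)


def translate_seq(seq: SymbolicSequence, frame: int = 0) -> ProteinSequence:
    """Translate with the standard genetic code; trailing partial codon dropped.

    In-frame stop codons are kept as ``*`` markers.
    """
    if seq.alphabet != ALPHA_DNA:
        raise ValueError("translation requires a DNA sequence")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    codes = seq.codes[frame:]
    n_codons = codes.size // 3
    if n_codons == 0:
        raise ValueError("sequence too short to translate")
    triplets = codes[: n_codons * 3].reshape(n_codons, 3).astype(np.int64)
    idx = triplets[:, 0] * 16 + triplets[:, 1] * 4 + triplets[:, 2]
    return ProteinSequence("".join(_AA_OF_CODON[idx]), seq.identifier)


def reverse_translate_random(
    protein: ProteinSequence, seed: int | np.random.Generator
) -> SymbolicSequence:
    """Replace each residue by a uniformly chosen synonymous codon (seeded)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residues = np.frombuffer(protein.residues.encode("ascii"), dtype=np.uint8)
    out = np.empty((len(protein), 3), dtype=np.uint8)
    # one vectorized uniform choice per residue type, in fixed (sorted) order
    for aa in sorted(CODONS_OF_AA):
        idx = np.flatnonzero(residues == ord(aa))
        if idx.size == 0:
            continue
        codons = CODONS_OF_AA[aa]
        table = np.array(
            [[_CODE[c] for c in codon] for codon in codons], dtype=np.uint8
        )
        out[idx] = table[rng.integers(0, len(codons), size=idx.size)]
    return SymbolicSequence(out.reshape(-1), ALPHA_DNA, protein.identifier)


def back_and_forth_test(
    seq: SymbolicSequence,
    seed: int,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    dfa_fit_min: float = 2000.0,
) -> tuple[SymbolicSequence, dict]:
    """Translate (frame 0), reverse-translate randomly, and compare statistics.

    The report contrasts, before vs after, the strong-class per-segment
    moments (<n>, sigma_n, rho), and the DFA2 exponent of the
    bond-enthalpy track over large scales.  The encoded protein is
    identical by construction.
    """
    protein = translate_seq(seq, frame=0)
    recon = reverse_translate_random(protein, seed)

    def summarize(s: SymbolicSequence) -> dict:
        prof = segment_counts(s, segment_length)
        st = segment_stats(prof, "S")
        fl = fluctuation_function(encode_enthalpy(s).values)
        h_large = estimate_hurst(fl, s_min=min(dfa_fit_min, fl.scales[-4]))
        return {
            "mean_n": st.mean_n,
            "sigma_n": st.sigma_n,
            "rho": st.rho,
            "gc": s.gc_content(),
            "hurst_large_scale": h_large,
        }

    report = {
        "original": summarize(seq),
        "reconstructed": summarize(recon),
        "protein_length": len(protein),
    }
    return recon, report


#: a predictor maps the history (array of past per-segment fractions) to
#: the next segment's predicted fraction
Predictor = Callable[[np.ndarray], float]


def ewma_predictor(half_life: float = 5.0) -> Predictor:
    """Exponentially weighted average of past segment fractions.

    The most recent segments dominate (weight halves every ``half_life``
    segments), so slow composition drifts are tracked while the prediction
    stays inside the observed range.
    """
    decay = 0.5 ** (1.0 / half_life)

    def predict(history: np.ndarray) -> float:
        if history.size == 0:
            raise ValueError("empty history")
        weights = decay ** np.arange(history.size - 1, -1, -1)
        return float(np.clip(np.sum(weights * history) / np.sum(weights), 0.0, 1.0))

    return predict


def predict_segment_targets(
    host_profile: SegmentProfile,
    n_future: int,
    predictor: Predictor | None = None,
) -> SegmentTargets:
    """Extrapolate host-DNA local fractions over the next ``n_future`` segments.

    One-segment-ahead prediction, iterated: each predicted value is
    appended to the history before the next segment is predicted.  The
    predictor is pluggable so alternative extrapolation rules can be
    dropped in; the default is :func:`ewma_predictor`.
    """
    if host_profile.n_seg < 2:
        raise ValueError("need at least 2 host segments")
    predictor = predictor or ewma_predictor()
    L = host_profile.segment_length
    with np.errstate(invalid="ignore", divide="ignore"):
        n_w = host_profile.counts["W"].astype(np.float64)
        n_s = host_profile.counts["S"].astype(np.float64)
        series = {
            "xi_s": n_s / L,
            "a_of_w": np.where(n_w > 0, host_profile.counts["A"] / n_w, 0.5),
            "g_of_s": np.where(n_s > 0, host_profile.counts["G"] / n_s, 0.5),
        }
    out = {key: [] for key in series}
    for key, hist in series.items():
        history = list(hist)
        for _ in range(n_future):
            nxt = predictor(np.asarray(history))
            out[key].append(nxt)
            history.append(nxt)
    return SegmentTargets(
        np.array(out["xi_s"]), np.array(out["a_of_w"]), np.array(out["g_of_s"]), L
    )


_S_OF_CODE = np.array([0, 1, 1, 0], dtype=np.int64)  # A,C,G,T -> strong?
_A_OF_CODE = np.array([1, 0, 0, 0], dtype=np.int64)
_G_OF_CODE = np.array([0, 0, 1, 0], dtype=np.int64)


def reverse_translate_guided(
    protein: ProteinSequence,
    targets: SegmentTargets,
    seed: int | np.random.Generator = 0,
) -> SymbolicSequence:
    """Greedy codon choice steering local composition toward segment targets.

    Left to right, each residue's synonymous codon is scored by the squared
    displacement of the running strong-fraction of the current design
    segment (the segment holding the codon's first base) from that
    segment's target; ties are broken by the purine/pyrimidine criteria
    (A-among-weak and G-among-strong squared displacements), and any
    remaining ties by a seeded random choice.  Translating the result
    reproduces the input protein exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = targets.segment_length
    needed = -(-3 * len(protein) // L)
    if len(targets) < needed:
        raise ValueError(
            f"targets cover {len(targets)} segments, need {needed} "
            f"for {len(protein)} residues"
        )

    codon_codes = {
        aa: np.array([[_CODE[c] for c in codon] for codon in codons], dtype=np.int64)
        for aa, codons in CODONS_OF_AA.items()
    }

    out = np.empty(3 * len(protein), dtype=np.uint8)
    pos = 0
    # running per-segment tallies: positions filled, strong, A, weak, G
    filled = np.zeros(len(targets), dtype=np.int64)
    tally = {
        "s": np.zeros(len(targets), dtype=np.int64),
        "w": np.zeros(len(targets), dtype=np.int64),
        "a": np.zeros(len(targets), dtype=np.int64),
        "g": np.zeros(len(targets), dtype=np.int64),
    }
    for aa in protein.residues:
        cands = codon_codes[aa]
        seg = pos // L
        add_s = _S_OF_CODE[cands].sum(axis=1)
        new_filled = filled[seg] + 3
        xi_run = (tally["s"][seg] + add_s) / new_filled
        primary = (xi_run - targets.xi_s[seg]) ** 2
        best = primary <= primary.min() + 1e-12
        if best.sum() > 1:
            add_a = _A_OF_CODE[cands].sum(axis=1)
            add_g = _G_OF_CODE[cands].sum(axis=1)
            add_w = 3 - add_s
            new_w = tally["w"][seg] + add_w
            new_strong = tally["s"][seg] + add_s
            with np.errstate(invalid="ignore", divide="ignore"):
                a_frac = np.where(
                    new_w > 0, (tally["a"][seg] + add_a) / new_w, targets.a_of_w[seg]
                )
                g_frac = np.where(
                    new_strong > 0,
                    (tally["g"][seg] + add_g) / new_strong,
                    targets.g_of_s[seg],
                )
            secondary = (a_frac - targets.a_of_w[seg]) ** 2 + (
                g_frac - targets.g_of_s[seg]
            ) ** 2
            secondary = np.where(best, secondary, np.inf)
            best = secondary <= secondary.min() + 1e-12
        choice_pool = np.flatnonzero(best)
        choice = int(choice_pool[rng.integers(0, choice_pool.size)])
        codon = cands[choice]
        out[pos : pos + 3] = codon
        # attribute each base to the segment it actually lands in
        for offset in range(3):
            g = (pos + offset) // L
            if g >= len(targets):
                g = len(targets) - 1
            c = int(codon[offset])
            filled[g] += 1
            tally["s"][g] += int(_S_OF_CODE[c])
            tally["w"][g] += 1 - int(_S_OF_CODE[c])
            tally["a"][g] += int(_A_OF_CODE[c])
            tally["g"][g] += int(_G_OF_CODE[c])
        pos += 3
    return SymbolicSequence(out, ALPHA_DNA, protein.identifier)


def segment_target_mse(
    seq: SymbolicSequence, targets: SegmentTargets
) -> float:
    """Mean squared deviation of realized per-segment strong fractions
    from the targets (partial trailing segment included pro rata)."""
    L = targets.segment_length
    n = len(seq)
    n_full = n // L
    sw = _S_OF_CODE[seq.codes.astype(np.int64)]
    devs = []
    for i in range(min(n_full, len(targets))):
        xi = sw[i * L : (i + 1) * L].mean()
        devs.append((xi - targets.xi_s[i]) ** 2)
    if n_full < len(targets) and n > n_full * L:
        xi = sw[n_full * L :].mean()
        devs.append((xi - targets.xi_s[n_full]) ** 2)
    return float(np.mean(devs))
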