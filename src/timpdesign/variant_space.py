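"""Reference scheme, variant signatures, encodings, and mutational-space enumeration.

A protein variant library mutates a small set of interface positions of a
wild-type (WT) scaffold.  A *signature* is the tuple of residues at those
targeted positions, in ascending position order; it is the unit of counting,
modeling, and design throughout this package.  The default scheme targets the
seven N-TIMP2 interface positions 4, 35, 38, 68, 71, 97 and 99 (mature-protein
numbering, first residue = position 1), whose WT residues are S, I, N, S, V,
H, T.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml
from Bio import SeqIO

#: Canonical amino-acid alphabet, fixed order for reproducible encodings.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Default targeted interface positions (1-based, mature-protein numbering).
DEFAULT_POSITIONS: tuple[int, ...] = (4, 35, 38, 68, 71, 97, 99)

#: WT residues at the default positions.
DEFAULT_WT_SIGNATURE: str = "SINSVHT"


class RejectionReason(str, Enum):
    """Why a read was excluded from signature counting."""

    OFF_TARGET_MUTATION = "OFF_TARGET_MUTATION"
    TOO_SHORT = "TOO_SHORT"
    INVALID_RESIDUE = "INVALID_RESIDUE"


@dataclass(frozen=True)
class Rejection:
    reason: RejectionReason


@dataclass(frozen=True)
class ReferenceScheme:
    """WT sequence plus the ordered positions where the library mutates it.

    Parameters
    ----------
    wt_sequence:
        Full-length WT amino-acid sequence (position 1 = first residue).
    targeted_positions:
        Strictly increasing 1-based positions allowed to vary.
    alphabet:
        Ordered residue alphabet used for encodings and enumeration.
    """

    wt_sequence: str
    targeted_positions: tuple[int, ...] = DEFAULT_POSITIONS
    alphabet: tuple[str, ...] = AMINO_ACIDS

    def __post_init__(self) -> None:
        positions = tuple(self.targeted_positions)
        object.__setattr__(self, "targeted_positions", positions)
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("targeted positions must be strictly increasing")
        if not positions or positions[0] < 1 or positions[-1] > len(self.wt_sequence):
            raise ValueError("targeted positions must lie within the WT sequence")
        bad = set(self.wt_sequence) - set(self.alphabet)
        if bad:
            raise ValueError(f"WT sequence contains non-alphabet residues: {sorted(bad)}")

    @property
    def n_positions(self) -> int:
        return len(self.targeted_positions)

    @property
    def wt_signature(self) -> str:
        return "".join(self.wt_sequence[p - 1] for p in self.targeted_positions)

    @property
    def alphabet_index(self) -> dict[str, int]:
        return {aa: i for i, aa in enumerate(self.alphabet)}

    def num_mutations(self, signature: str) -> int:
        """Hamming distance of a signature from the WT signature."""
        self.validate_signature(signature)
        return sum(a != b for a, b in zip(signature, self.wt_signature))

    def validate_signature(self, signature: str) -> None:
        if len(signature) != self.n_positions:
            raise ValueError(
                f"signature length {len(signature)} != {self.n_positions} targeted positions"
            )
        bad = set(signature) - set(self.alphabet)
        if bad:
            raise ValueError(f"signature contains non-alphabet residues: {sorted(bad)}")

    def full_sequence(self, signature: str) -> str:
        """Expand a signature back into a full-length sequence."""
        self.validate_signature(signature)
        seq = list(self.wt_sequence)
        for pos, aa in zip(self.targeted_positions, signature):
            seq[pos - 1] = aa
        return "".join(seq)

    def to_dict(self) -> dict:
        return {
            "wt_sequence": self.wt_sequence,
            "positions": list(self.targeted_positions),
            "alphabet": "".join(self.alphabet),
        }


def scheme_from_dict(data: dict) -> ReferenceScheme:
    """Build a scheme from a config mapping (``wt_sequence`` or ``fasta`` path)."""
    if "wt_sequence" in data:
        wt = data["wt_sequence"]
    elif "fasta" in data:
        record = next(SeqIO.parse(Path(data["fasta"]), "fasta"))
        wt = str(record.seq)
    else:
        raise KeyError("scheme config needs 'wt_sequence' or 'fasta'")
    kwargs = {}
    if "positions" in data:
        kwargs["targeted_positions"] = tuple(int(p) for p in data["positions"])
    if "alphabet" in data:
        kwargs["alphabet"] = tuple(data["alphabet"])
    return ReferenceScheme(wt_sequence=wt, **kwargs)


def load_scheme(path: str | Path) -> ReferenceScheme:
    """Load a reference scheme from a YAML/JSON file."""
    with open(path) as handle:
        return scheme_from_dict(yaml.safe_load(handle))


def signature_of(full_sequence: str, scheme: ReferenceScheme) -> str | Rejection:
    """Extract a variant signature from a full-length read.

    A read is accepted only if it is at least WT length, contains only
    alphabet residues over the WT span, and matches WT at every non-targeted
    position; everything else is returned as a :class:`Rejection` so callers
    can tally filtering statistics.
    """
    wt = scheme.wt_sequence
    if len(full_sequence) < len(wt):
        return Rejection(RejectionReason.TOO_SHORT)
    seq = full_sequence[: len(wt)]
    alphabet = set(scheme.alphabet)
    if any(aa not in alphabet for aa in seq):
        return Rejection(RejectionReason.INVALID_RESIDUE)
    targeted = set(scheme.targeted_positions)
    for i, (aa, wt_aa) in enumerate(zip(seq, wt), start=1):
        if aa != wt_aa and i not in targeted:
            return Rejection(RejectionReason.OFF_TARGET_MUTATION)
    return "".join(seq[p - 1] for p in scheme.targeted_positions)


def one_hot(signature: str, scheme: ReferenceScheme) -> np.ndarray:
    """One-hot encode a signature: position-major blocks of ``len(alphabet)``."""
    scheme.validate_signature(signature)
    index = scheme.alphabet_index
    a = len(scheme.alphabet)
    vec = np.zeros(a * scheme.n_positions, dtype=np.float64)
    for p, aa in enumerate(signature):
        vec[p * a + index[aa]] = 1.0
    return vec


def one_hot_batch(signatures: Sequence[str], scheme: ReferenceScheme) -> np.ndarray:
    """Vectorised one-hot encoding, one row per signature."""
    a = len(scheme.alphabet)
    n = scheme.n_positions
    if len(signatures) == 0:
        return np.zeros((0, a * n), dtype=np.float64)
    joined = "".join(signatures)
    if len(joined) != n * len(signatures):
        raise ValueError("all signatures must match the scheme's position count")
    codes = np.frombuffer(joined.encode("ascii"), dtype=np.uint8).reshape(-1, n)
    lookup = np.full(128, -1, dtype=np.int64)
    for i, aa in enumerate(scheme.alphabet):
        lookup[ord(aa)] = i
    idx = lookup[codes]
    if (idx < 0).any():
        raise ValueError("signature contains non-alphabet residues")
    out = np.zeros((len(signatures), a * n), dtype=np.float64)
    rows = np.repeat(np.arange(len(signatures)), n)
    cols = (np.arange(n) * a + idx).ravel()
    out[rows, cols] = 1.0
    return out


def decode_one_hot(vector: np.ndarray, scheme: ReferenceScheme) -> str:
    """Inverse of :func:`one_hot` via per-block argmax."""
    a = len(scheme.alphabet)
    blocks = np.asarray(vector).reshape(scheme.n_positions, a)
    return "".join(scheme.alphabet[int(i)] for i in blocks.argmax(axis=1))


def theoretical_variant_count(k: int, n_positions: int = 7, alphabet_size: int = 20) -> int:
    """Size of the k-mutation stratum under the C(n, k) * a^k convention.

    Counts choices of k mutated positions times the full alphabet at each
    chosen position.  This is the convention used in published library
    inventories; note it admits the WT letter at a "mutated" position and so
    double-counts lower-order variants (e.g. k=1 gives 7*20 = 140, not 7*19).
    """
    if not 0 <= k <= n_positions:
        raise ValueError(f"k={k} out of range 0..{n_positions}")
    return math.comb(n_positions, k) * alphabet_size**k


def enumerate_fully_mutated(
    scheme: ReferenceScheme,
    batch_positions: tuple[int, int] | None = None,
) -> Iterator[list[str]]:
    """Stream every signature mutated (non-WT) at *all* targeted positions.

    The space of size ``(a-1)^n`` is yielded in ``(a-1)^2`` batches: the two
    ``batch_positions`` are fixed to one non-WT residue each per batch and the
    remaining positions run over all their non-WT residues.  Every signature
    appears in exactly one batch, so the union over batches is duplicate-free.
    Defaults to batching on the last two targeted positions.
    """
    positions = scheme.targeted_positions
    if batch_positions is None:
        batch_positions = (positions[-2], positions[-1])
    if len(set(batch_positions)) != 2 or any(p not in positions for p in batch_positions):
        raise ValueError(f"batch positions must be two distinct targeted positions, got {batch_positions}")

    wt_sig = scheme.wt_signature
    # Per targeted-position index: the non-WT residues, in alphabet order.
    non_wt = [
        [aa for aa in scheme.alphabet if aa != wt_sig[i]]
        for i in range(scheme.n_positions)
    ]
    batch_idx = sorted(positions.index(p) for p in batch_positions)
    free_idx = [i for i in range(scheme.n_positions) if i not in batch_idx]

    for fixed in itertools.product(*(non_wt[i] for i in batch_idx)):
        batch: list[str] = []
        template = [""] * scheme.n_positions
        for i, aa in zip(batch_idx, fixed):
            template[i] = aa
        for combo in itertools.product(*(non_wt[i] for i in free_idx)):
            for i, aa in zip(free_idx, combo):
                template[i] = aa
            batch.append("".join(template))
        yield batch


def fully_mutated_space_size(scheme: ReferenceScheme) -> int:
    return (len(scheme.alphabet) - 1) ** scheme.n_positions


def sample_variant_space(
    scheme: ReferenceScheme, n: int, seed: int | np.random.Generator
) -> list[str]:
    """Draw ``n`` signatures i.i.d. uniformly over ``alphabet^n_positions``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(scheme.alphabet)
    draws = rng.integers(0, len(letters), size=(n, scheme.n_positions))
    return ["".join(row) for row in letters[draws]]


def enumerate_full_space(scheme: ReferenceScheme) -> Iterator[str]:
    """Exhaustive enumeration of ``alphabet^n_positions`` (reduced schemes only)."""
    for combo in itertools.product(scheme.alphabet, repeat=scheme.n_positions):
        yield "".join(combo)


def mutation_count_inventory(signatures: Iterable[str], scheme: ReferenceScheme) -> dict[int, int]:
    """Tally signatures by their number of mutations (library-inventory style)."""
    inventory: dict[int, int] = {}
    for sig in signatures:
        k = scheme.num_mutations(sig)
        inventory[k] = inventory.get(k, 0) + 1
    return dict(sorted(inventory.items()))
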