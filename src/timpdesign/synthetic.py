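"""Synthetic sort-seq and kinetics data with planted ground truth.

Every pipeline stage in this package can be exercised without external data:
this module fabricates a reference scheme, draws an additive (optionally
epistatic) fitness landscape standing in for true binding energy, simulates
affinity-dependent two-gate sorting with finite-depth read sampling, emits
raw FASTA reads that exercise the library filters, and generates Morrison
inhibition curves at known Ki.

The sorting abstraction: each displayed variant enters the High gate with
probability logistic((energy - mu)/tau) and the Low gate otherwise, and each
gate is sequenced to a configured read depth by multinomial sampling.  In
the deep-read limit the measured log2 enrichment ratio of the High gate
converges to log2 p_high(v) - log2 p_high(WT), which is what
:func:`true_log2_er` returns as ground truth.

Defaults state a realistic desk-scale experiment: 5000 distinct library
variants, 10^6 reads per gate, and a library mutation-number mix matching a
published single-mutation-centred saturation library inventory (dominated by
double and triple mutants, with few quadruples and a lone quintuple).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrichment import GateCountTable, GateLabel, PRESORT, Stringency
from .kinetics import InhibitionCurve, ki_to_kiapp, morrison_relative_velocity
from .variant_space import DEFAULT_POSITIONS, DEFAULT_WT_SIGNATURE, ReferenceScheme

#: Mutation-number proportions of the emulated original library
#: (counts 131/3142/1526/81/1 over 4881 mutant variants).
DEFAULT_MUTATION_MIX: dict[int, float] = {
    1: 131 / 4881,
    2: 3142 / 4881,
    3: 1526 / 4881,
    4: 81 / 4881,
    5: 1 / 4881,
}


def make_reference_scheme(seed: int = 20_260_101, length: int = 127) -> ReferenceScheme:
    """Fabricate a synthetic WT reference sequence (NOT the real scaffold).

    A random 127-residue sequence with the canonical WT interface residues
    S, I, N, S, V, H, T planted at positions 4, 35, 38, 68, 71, 97, 99.  The
    scaffold outside the targeted positions is arbitrary: only the targeted
    positions matter to any computation in this package.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq = list(alphabet[rng.integers(0, 20, size=length)])
    for pos, aa in zip(DEFAULT_POSITIONS, DEFAULT_WT_SIGNATURE):
        seq[pos - 1] = aa
    return ReferenceScheme(wt_sequence="".join(seq))


# ---------------------------------------------------------------------------
# Fitness landscapes
# ---------------------------------------------------------------------------

@dataclass
class FitnessLandscape:
    """Additive per-position energies plus optional sparse pairwise epistasis.

    ``energies[p, a]`` is the energy contribution of alphabet letter ``a`` at
    targeted-position index ``p`` (WT letters fixed at 0, so energy(WT) = 0).
    ``epistasis[(p, q)][a, b]`` adds an interaction term for the letter pair;
    rows/columns of WT letters are zero so additivity of WT-containing pairs
    is preserved.
    """

    scheme: ReferenceScheme
    energies: np.ndarray
    epistasis: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        index = self.scheme.alphabet_index
        wt = self.scheme.wt_signature
        for p, aa in enumerate(wt):
            assert self.energies[p, index[aa]] == 0.0, "WT energies must be zero"

    def energy(self, signature: str) -> float:
        return float(self.energy_batch([signature])[0])

    def energy_batch(self, signatures: Sequence[str]) -> np.ndarray:
        index = self.scheme.alphabet_index
        idx = np.array([[index[aa] for aa in sig] for sig in signatures])
        out = self.energies[np.arange(idx.shape[1]), idx].sum(axis=1)
        for (p, q), table in self.epistasis.items():
            out = out + table[idx[:, p], idx[:, q]]
        return out


def make_landscape(
    scheme: ReferenceScheme,
    seed: int,
    epistasis_pairs: int = 0,
    effect_sd: float = 1.0,
) -> FitnessLandscape:
    """Draw i.i.d. normal(0, effect_sd) energies; WT entries zeroed."""
    if effect_sd <= 0:
        raise ValueError("effect_sd must be positive")
    rng = np.random.default_rng(seed)
    a = len(scheme.alphabet)
    n = scheme.n_positions
    energies = rng.normal(0.0, effect_sd, size=(n, a))
    index = scheme.alphabet_index
    for p, aa in enumerate(scheme.wt_signature):
        energies[p, index[aa]] = 0.0
    epistasis: dict[tuple[int, int], np.ndarray] = {}
    if epistasis_pairs > 0:
        pairs = [(p, q) for p in range(n) for q in range(p + 1, n)]
        chosen = rng.choice(len(pairs), size=min(epistasis_pairs, len(pairs)), replace=False)
        for c in chosen:
            p, q = pairs[c]
            table = rng.normal(0.0, effect_sd, size=(a, a))
            table[index[scheme.wt_signature[p]], :] = 0.0
            table[:, index[scheme.wt_signature[q]]] = 0.0
            epistasis[(p, q)] = table
    return FitnessLandscape(scheme=scheme, energies=energies, epistasis=epistasis)


# ---------------------------------------------------------------------------
# Library and sorting simulation
# ---------------------------------------------------------------------------

@dataclass
class SortSimulationConfig:
    """Stated world of the synthetic sort-seq experiment."""

    n_variants: int = 5000
    reads_per_gate: int = 1_000_000
    mutation_mix: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_MIX)
    )
    gate_mu: float = 0.0
    gate_tau: float = 1.0
    off_target_mutation_rate: float = 0.0
    truncation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_gate < 0 or self.n_variants < 1:
            raise ValueError("reads and variant count must be non-negative/positive")
        total = sum(self.mutation_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("mutation_mix probabilities must sum to 1")
        for rate in (self.off_target_mutation_rate, self.truncation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def sample_library(scheme: ReferenceScheme, config: SortSimulationConfig) -> dict[str, int]:
    """Draw a presort library composition (signature -> abundance).

    Each draw picks a mutation count from the configured mix, then mutated
    positions uniformly without replacement, then a non-WT letter uniformly
    at each.  Duplicate draws accumulate abundance; WT is always present.
    """
    rng = np.random.default_rng(config.seed)
    wt = scheme.wt_signature
    ks = sorted(config.mutation_mix)
    probs = np.array([config.mutation_mix[k] for k in ks])
    non_wt = [
        [aa for aa in scheme.alphabet if aa != wt[i]] for i in range(scheme.n_positions)
    ]
    composition: dict[str, int] = {wt: 1}
    draws = rng.choice(ks, size=config.n_variants, p=probs)
    for k in draws:
        positions = rng.choice(scheme.n_positions, size=int(k), replace=False)
        sig = list(wt)
        for p in positions:
            letters = non_wt[p]
            sig[p] = letters[int(rng.integers(0, len(letters)))]
        sig_s = "".join(sig)
        composition[sig_s] = composition.get(sig_s, 0) + 1
    return composition


def gate_probability_high(
    energies: np.ndarray, mu: float, tau: float
) -> np.ndarray:
    """Probability that a variant sorts into the High gate (logistic in energy)."""
    if tau <= 0:
        # Step-gate limit: strictly above mu goes High, at/below goes Low.
        return (energies > mu).astype(np.float64)
    return 1.0 / (1.0 + np.exp(-(energies - mu) / tau))


def simulate_sort_counts(
    library: Mapping[str, int],
    landscape: FitnessLandscape,
    config: SortSimulationConfig,
    target: str = "TARGET",
) -> dict[Stringency, GateCountTable]:
    """Multinomial read sampling of PreSort / Low / High gate tables.

    Expected reads: PreSort proportional to abundance; High proportional to
    abundance * p_high(energy); Low proportional to abundance * (1 - p_high).
    Each gate is sampled to ``config.reads_per_gate`` total reads.
    """
    rng = np.random.default_rng(config.seed + 1)
    signatures = sorted(library)
    abundance = np.array([library[s] for s in signatures], dtype=np.float64)
    energies = landscape.energy_batch(signatures)
    p_high = gate_probability_high(energies, config.gate_mu, config.gate_tau)

    def draw(weights: np.ndarray, gate: GateLabel) -> GateCountTable:
        total = weights.sum()
        if total <= 0 or config.reads_per_gate == 0:
            return GateCountTable(gate=gate, counts={})
        counts = rng.multinomial(config.reads_per_gate, weights / total)
        return GateCountTable(
            gate=gate,
            counts={s: int(c) for s, c in zip(signatures, counts) if c > 0},
        )

    return {
        Stringency.PRESORT: draw(abundance, PRESORT),
        Stringency.LOW: draw(abundance * (1.0 - p_high), GateLabel(target, Stringency.LOW)),
        Stringency.HIGH: draw(abundance * p_high, GateLabel(target, Stringency.HIGH)),
    }


def true_log2_er(
    signatures: Sequence[str],
    landscape: FitnessLandscape,
    config: SortSimulationConfig,
    stringency: Stringency = Stringency.HIGH,
) -> np.ndarray:
    """Deep-read-limit log2 ER: log2 p_gate(v) - log2 p_gate(WT)."""
    energies = landscape.energy_batch(list(signatures) + [landscape.scheme.wt_signature])
    p_high = gate_probability_high(energies, config.gate_mu, config.gate_tau)
    p_gate = p_high if stringency is Stringency.HIGH else 1.0 - p_high
    with np.errstate(divide="ignore"):
        log_p = np.log2(p_gate)
    return log_p[:-1] - log_p[-1]


# ---------------------------------------------------------------------------
# Raw reads
# ---------------------------------------------------------------------------

def emit_reads(
    table: Mapping[str, int],
    scheme: ReferenceScheme,
    config: SortSimulationConfig,
    gate_name: str = "Gate_PreSort",
) -> Iterable[tuple[str, str]]:
    """Yield (header, sequence) full-length reads for a count table.

    With probability ``off_target_mutation_rate`` a read gets a substitution
    at a random non-targeted position (guaranteed different from WT); with
    probability ``truncation_rate`` it is truncated below WT length.  Headers
    carry the gate, the truth signature, and a per-read ordinal, so tests can
    introspect the ground truth of every read.
    """
    rng = np.random.default_rng(config.seed + 2)
    targeted = set(scheme.targeted_positions)
    non_targeted = [i for i in range(1, len(scheme.wt_sequence) + 1) if i not in targeted]
    read_no = 0
    for signature in sorted(table):
        full = scheme.full_sequence(signature)
        for _ in range(table[signature]):
            read_no += 1
            seq = full
            flags = []
            if config.off_target_mutation_rate > 0 and rng.random() < config.off_target_mutation_rate:
                pos = non_targeted[int(rng.integers(0, len(non_targeted)))]
                current = seq[pos - 1]
                choices = [aa for aa in scheme.alphabet if aa != current]
                seq = seq[: pos - 1] + choices[int(rng.integers(0, len(choices)))] + seq[pos:]
                flags.append("offtarget")
            if config.truncation_rate > 0 and rng.random() < config.truncation_rate:
                cut = int(rng.integers(1, len(scheme.wt_sequence)))
                seq = seq[:cut]
                flags.append("truncated")
            header = f"{gate_name}|sig={signature}|read={read_no}"
            if flags:
                header += "|" + ",".join(flags)
            yield header, seq


def write_reads_fasta(
    table: Mapping[str, int],
    scheme: ReferenceScheme,
    config: SortSimulationConfig,
    path: str | Path,
    gate_name: str = "Gate_PreSort",
) -> None:
    with open(path, "w") as handle:
        for header, seq in emit_reads(table, scheme, config, gate_name):
            handle.write(f">{header}\n{seq}\n")


# ---------------------------------------------------------------------------
# Kinetics simulation
# ---------------------------------------------------------------------------

def simulate_inhibition_data(
    ki_nm: float,
    e_nm: float,
    s_um: float,
    km_um: float,
    i_grid_nm: Sequence[float],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> list[InhibitionCurve]:
    """Morrison curves at known Ki with multiplicative Gaussian noise."""
    if ki_nm <= 0 or e_nm <= 0:
        raise ValueError("Ki and E must be positive")
    rng = np.random.default_rng(seed)
    kiapp = ki_to_kiapp(ki_nm, s_um, km_um)
    i_grid = np.asarray(i_grid_nm, dtype=np.float64)
    curves = []
    for rep in range(replicates):
        v = morrison_relative_velocity(e_nm, i_grid, kiapp)
        if noise_sd > 0:
            v = v * (1.0 + rng.normal(0.0, noise_sd, size=v.shape))
        curves.append(
            InhibitionCurve(
                inhibitor_nm=i_grid.copy(),
                relative_velocity=np.clip(v, 0.0, 1.0),
                e_nm=e_nm,
                replicate=rep,
            )
        )
    return curves
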