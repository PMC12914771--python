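"""Per-variant frequencies, WT-normalized frequencies, and enrichment ratios.

Sort-seq experiments sequence an unsorted (PreSort) library and sorted gate
fractions.  For each variant j in a gate the pipeline computes

    f_j  = reads_j / total reads in the gate
    NF_j = f_j / f_WT                       (WT-normalized frequency)
    ER_j = NF_j(gate) / NF_j(PreSort)

and uses log2(ER) as the affinity-proxy training label.  WT has NF = 1 in
every gate and therefore ER = 1, log2 ER = 0, by construction.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .variant_space import ReferenceScheme, Rejection, signature_of


class Stringency(str, Enum):
    PRESORT = "PRESORT"
    LOW = "LOW"
    HIGH = "HIGH"


@dataclass(frozen=True)
class GateLabel:
    """Identifies one library fraction: a target enzyme and a sort stringency."""

    target: str
    stringency: Stringency

    def __str__(self) -> str:
        if self.stringency is Stringency.PRESORT:
            return "Gate_PreSort"
        return f"Gate_{self.target}_{self.stringency.value.capitalize()}"


PRESORT = GateLabel(target="", stringency=Stringency.PRESORT)


@dataclass
class GateCountTable:
    """Per-variant read counts for one library fraction."""

    gate: GateLabel
    counts: dict[str, int]
    rejection_stats: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def scaled(self, factor: int) -> "GateCountTable":
        return GateCountTable(
            gate=self.gate,
            counts={sig: c * factor for sig, c in self.counts.items()},
            rejection_stats=dict(self.rejection_stats),
        )


class EmptyGateError(ValueError):
    """Gate table has zero reads; frequencies are undefined."""


class WTMissingError(ValueError):
    """WT signature absent from a table; normalization is undefined."""


@dataclass(frozen=True)
class EnrichmentRecord:
    """All per-variant quantities of the frequency -> NF -> ER chain."""

    signature: str
    count_presort: int
    count_gate: int
    f_presort: float
    f_gate: float
    nf_presort: float
    nf_gate: float
    er: float
    log2_er: float


@dataclass(frozen=True)
class TrainingExample:
    """A labelled variant: signature, log2 ER label, raw read-count weight."""

    signature: str
    label: float
    weight_raw: int


def count_reads(
    sequences: Iterable[str], gate: GateLabel, scheme: ReferenceScheme
) -> GateCountTable:
    """Count accepted full-length reads per signature; tally rejections.

    Reads failing the library filters (off-target mutation, short read,
    non-alphabet residue) are excluded from the counts and recorded in
    ``rejection_stats`` so that accepted + rejected == input reads.
    """
    counts: Counter[str] = Counter()
    rejections: Counter[str] = Counter()
    for seq in sequences:
        result = signature_of(seq, scheme)
        if isinstance(result, Rejection):
            rejections[result.reason.value] += 1
        else:
            counts[result] += 1
    return GateCountTable(gate=gate, counts=dict(counts), rejection_stats=dict(rejections))


def count_reads_fasta(path: str | Path, gate: GateLabel, scheme: ReferenceScheme) -> GateCountTable:
    """As :func:`count_reads`, reading amino-acid reads from a FASTA file."""
    sequences = (str(rec.seq) for rec in SeqIO.parse(Path(path), "fasta"))
    return count_reads(sequences, gate, scheme)


def frequencies(table: GateCountTable) -> dict[str, float]:
    """Per-variant read frequencies; they sum to 1 over the table."""
    total = table.total_reads
    if total < 1:
        raise EmptyGateError(f"{table.gate} has no reads")
    return {sig: c / total for sig, c in table.counts.items()}


def normalized_frequencies(
    freqs: Mapping[str, float], scheme: ReferenceScheme
) -> dict[str, float]:
    """Divide every frequency by the WT frequency (WT maps to exactly 1)."""
    wt = scheme.wt_signature
    f_wt = freqs.get(wt, 0.0)
    if f_wt <= 0:
        raise WTMissingError("WT signature absent; normalized frequency undefined")
    return {sig: f / f_wt for sig, f in freqs.items()}


def enrichment_ratios(
    presort_table: GateCountTable,
    gate_table: GateCountTable,
    scheme: ReferenceScheme,
    pseudocount: float = 0.0,
    min_count: int = 1,
) -> tuple[list[EnrichmentRecord], dict[str, int]]:
    """Compute enrichment records for variants present in both fractions.

    With ``pseudocount`` alpha > 0 every count is replaced by count + alpha
    before the frequency step and presence is no longer required.  Excluded
    variants are tallied (NOT_IN_PRESORT / NOT_IN_GATE / BELOW_MIN_COUNT) and
    returned alongside the records.
    """

    def effective(table: GateCountTable, universe: Iterable[str]) -> dict[str, float]:
        if pseudocount > 0:
            return {sig: table.counts.get(sig, 0) + pseudocount for sig in universe}
        return {sig: float(c) for sig, c in table.counts.items()}

    universe = set(presort_table.counts) | set(gate_table.counts)
    pre_counts = effective(presort_table, universe)
    gate_counts = effective(gate_table, universe)

    excluded: Counter[str] = Counter()
    kept: list[str] = []
    for sig in sorted(universe):
        # With a pseudocount, presence (and the raw-count floor) is waived.
        pre_ok = pre_counts.get(sig, 0) > 0 and (
            pseudocount > 0 or presort_table.counts.get(sig, 0) >= min_count
        )
        gate_ok = gate_counts.get(sig, 0) > 0 and (
            pseudocount > 0 or gate_table.counts.get(sig, 0) >= min_count
        )
        if pre_ok and gate_ok:
            kept.append(sig)
        elif pre_counts.get(sig, 0) <= 0:
            excluded["NOT_IN_PRESORT"] += 1
        elif gate_counts.get(sig, 0) <= 0:
            excluded["NOT_IN_GATE"] += 1
        else:
            excluded["BELOW_MIN_COUNT"] += 1

    pre_total = sum(pre_counts.values())
    gate_total = sum(gate_counts.values())
    if pre_total <= 0 or gate_total <= 0:
        raise EmptyGateError("empty fraction")
    f_pre = {sig: pre_counts[sig] / pre_total for sig in pre_counts}
    f_gate = {sig: gate_counts[sig] / gate_total for sig in gate_counts}
    wt = scheme.wt_signature
    if f_pre.get(wt, 0) <= 0 or f_gate.get(wt, 0) <= 0:
        raise WTMissingError("WT signature must be present in both fractions")

    records = []
    for sig in kept:
        nf_pre = f_pre[sig] / f_pre[wt]
        nf_gate = f_gate[sig] / f_gate[wt]
        er = nf_gate / nf_pre
        records.append(
            EnrichmentRecord(
                signature=sig,
                count_presort=presort_table.counts.get(sig, 0),
                count_gate=gate_table.counts.get(sig, 0),
                f_presort=f_pre[sig],
                f_gate=f_gate[sig],
                nf_presort=nf_pre,
                nf_gate=nf_gate,
                er=er,
                log2_er=math.log2(er),
            )
        )
    return records, dict(excluded)


def build_training_table(records: Iterable[EnrichmentRecord]) -> list[TrainingExample]:
    """Label = log2 ER; raw weight = summed read count over the two fractions."""
    return [
        TrainingExample(
            signature=r.signature,
            label=r.log2_er,
            weight_raw=r.count_presort + r.count_gate,
        )
        for r in records
    ]


def records_to_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_enrichment_tsv(records: Iterable[EnrichmentRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_counts_tsv(path: str | Path, gate: GateLabel) -> GateCountTable:
    """Read a pre-tabulated (signature, count) TSV into a count table."""
    df = pd.read_csv(path, sep="\t", dtype={"signature": str})
    counts = dict(zip(df["signature"], df["count"].astype(int)))
    return GateCountTable(gate=gate, counts=counts)


def write_counts_tsv(table: GateCountTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.counts.items()), columns=["signature", "count"]
    ).to_csv(path, sep="\t", index=False)


def write_rejection_stats(table: GateCountTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(
            {"gate": str(table.gate), "rejections": table.rejection_stats},
            handle,
            indent=2,
            sort_keys=True,
        )
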