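"""Population recessive-genotype frequency under Hardy-Weinberg.

Per gene, the cumulative qualifying allele frequency is Q = sum(q_i)
(the sum rather than 1 - prod(1 - q_i): for q <= 1e-4 the difference is
below 1e-8 and cumulative MAFs are conventionally reported as sums).
Under random mating, the frequency of a biallelic (homozygous or
compound-heterozygous) genotype at an autosomal gene is Q^2; for an
X-linked gene, males are affected at frequency Q and females at Q^2,
so the population frequency is m*Q + (1 - m)*Q^2 for male fraction m.
Panel-level aggregates add across genes (rare-event additivity).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import PopFreqResult


def recessive_genotype_frequency(
    allele_freqs: Sequence[float],
    mode: str,
    gene: str = "",
    male_fraction: float = 0.5,
) -> PopFreqResult:
    """Cumulative MAF and recessive genotype frequency for one gene."""
    if mode not in ("autosomal", "x_linked"):
        raise ValueError("mode must be 'autosomal' or 'x_linked'")
    for q in allele_freqs:
        if not 0.0 <= q <= 0.5:
            raise ValueError(f"allele frequency {q} outside [0, 0.5]")
    big_q = float(sum(allele_freqs))
    if mode == "autosomal":
        freq = big_q**2
    else:
        freq = male_fraction * big_q + (1.0 - male_fraction) * big_q**2
    return PopFreqResult(
        gene=gene, cumulative_maf=big_q, genotype_frequency=freq,
        mode=mode, male_fraction=male_fraction,
    )


def panel_cumulative_frequency(
    results: Iterable[PopFreqResult],
) -> tuple[float, float]:
    """(aggregate genotype frequency, aggregate cumulative MAF) over genes."""
    seen: set[str] = set()
    total_freq = 0.0
    total_maf = 0.0
    for r in results:
        if r.gene in seen:
            raise ValueError(f"duplicate gene {r.gene}")
        seen.add(r.gene)
        total_freq += r.genotype_frequency
        total_maf += r.cumulative_maf
    return total_freq, total_maf
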