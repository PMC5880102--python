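"""Relative mtDNA abundance from qPCR Ct tables by the delta-delta-Ct method.

Amplification efficiency is fixed at 2.0 (classic ddCt), so
``log2_fc = -(dCt_tumor - dCt_peritumor)`` exactly.  Targets are always
reported separately, never averaged across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import QpcrTable


@dataclass
class MtDNAResult:
    tumor_sample: str
    peritumor_sample: str
    target: str
    delta_ct_tumor: float
    delta_ct_peritumor: float
    ddct: float
    log2_fc: float


def average_ct(replicates: list[float]) -> float:
    """Arithmetic mean of technical-replicate Ct values."""
    if not replicates:
        raise ValueError("cannot average an empty replicate list")
    return float(sum(replicates) / len(replicates))


def delta_delta_ct(
    table: QpcrTable,
    targets: list[str],
    reference_gene: str,
    pairs: list[tuple[str, str]],
) -> tuple[list[MtDNAResult], list[tuple[tuple[str, str], str]]]:
    """Per (pair, target): dCt = mean Ct(target) - mean Ct(reference) within
    each sample, ddCt = dCt_tumor - dCt_peritumor, log2_fc = -ddCt.

    A pair whose member is entirely absent from the table is omitted with a
    recorded reason; a present sample that lacks a required gene is an error
    naming sample and gene.
    """
    samples = set(table.samples)
    results: list[MtDNAResult] = []
    omitted: list[tuple[tuple[str, str], str]] = []

    def dct(sample: str, target: str) -> float:
        for gene in (target, reference_gene):
            if gene not in table.genes_for(sample):
                raise ValueError(f"sample {sample!r} is missing gene {gene!r}")
        return average_ct(table.replicates(sample, target)) - average_ct(
            table.replicates(sample, reference_gene)
        )

    for tumor, peritumor in pairs:
        absent = [s for s in (tumor, peritumor) if s not in samples]
        if absent:
            omitted.append(((tumor, peritumor), f"missing sample block(s): {absent}"))
            continue
        for target in targets:
            dct_t = dct(tumor, target)
            dct_p = dct(peritumor, target)
            ddct = dct_t - dct_p
            results.append(
                MtDNAResult(
                    tumor_sample=tumor,
                    peritumor_sample=peritumor,
                    target=target,
                    delta_ct_tumor=dct_t,
                    delta_ct_peritumor=dct_p,
                    ddct=ddct,
                    log2_fc=-ddct,
                )
            )
    return results, omitted
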