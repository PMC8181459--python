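#!/usr/bin/env python
"""Forensic characterization of the two study groups from their
published haplotype occurrence spectra.

The per-population spectra (how many haplotypes were seen once, twice,
...) fully determine every haplotype-level forensic parameter, so tables
realizing them exactly reproduce the reported MP, DC and FUH without the
deposited genotypes.  Writes results/forensic_summary.tsv.
"""

from pathlib import Path

from ystrkit.forensic import OccurrenceSpectrum, forensic_report, haplotype_diversity
from ystrkit.haplotypes import HaplotypeTable
from ystrkit.simulate import generate_spectrum_table

RESULTS = Path(__file__).resolve().parent.parent / "results"

SPECTRA = {
    "Hakka": {1: 208, 2: 18, 3: 4, 4: 1},
    "She": {1: 65, 2: 43, 3: 6, 4: 5, 5: 1, 6: 1, 15: 1},
}


def main() -> None:
    tables = []
    offset = 0
    for pop, counts in SPECTRA.items():
        t = generate_spectrum_table(OccurrenceSpectrum(counts), seed=len(pop), population=pop)
        # re-id samples so the two tables can be merged
        tables.extend(
            type(h)(f"M{offset + i:04d}", h.population, h.calls)
            for i, h in enumerate(t.haplotypes)
        )
        offset += len(t)
    merged = HaplotypeTable(t.panel, tables)
    report = forensic_report(merged)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "forensic_summary.tsv"
    report.summary.to_csv(out, sep="\t", index=False, float_format="%.6g")

    print("Haplotype-level forensic parameters (from occurrence spectra):")
    print(report.summary.round(4).to_string(index=False))
    print()
    for pop in SPECTRA:
        hd = haplotype_diversity(report.spectra[pop])
        print(f"{pop}: HD by n/(n-1)(1-MP) = {hd:.5f}")
    print()
    print(
        "Finding: the Hakka sample discriminates far better (DC 0.8885, 231\n"
        "distinct haplotypes in 260 men) than the She sample (DC 0.5674, 122\n"
        "in 215), whose spectrum is dominated by shared haplotypes - one is\n"
        "carried by 15 men - consistent with an isolated group with limited\n"
        "gene flow."
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
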