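"""Generate the synthetic two-colour skin experiment used by the
downstream analysis scripts.

Writes a complete bundle (genome with planted hairpins, contaminant
reference sets, white/brown FASTQ libraries, mature/hairpin catalogues,
target transcripts, qPCR CT table, truth tables) to results/sim/.
"""

from pathlib import Path

from mirskin.simulate import SimulationConfig, build_genome, simulate_libraries, write_bundle

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = 2024
N_READS = 50_000  # desk-scale stand-in for the ~1.7e7-read libraries


def main() -> None:
    config = SimulationConfig(n_reads=N_READS, seed=SEED)
    data = build_genome(config)
    libraries = simulate_libraries(data)
    write_bundle(data, libraries, OUT)
    truth = data.truth
    n_known = sum(1 for p in truth.planted_mirnas if p.kind == "known")
    n_novel = len(truth.planted_mirnas) - n_known
    n_de = len(truth.de_ids(2.0))
    print(f"wrote {OUT}")
    print(f"planted: {n_known} known miRNAs ({n_de} with FC >= 2), "
          f"{n_novel} novel precursors, {len(truth.decoy_ids)} decoy loci")
    print(f"libraries: {', '.join(f'{k} ({len(v)} reads)' for k, v in libraries.items())}")


if __name__ == "__main__":
    main()
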