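#!/usr/bin/env python
"""Simulate the study population and arrays.

Generates an intermated B73 x Mo17 doubled-haploid population (135 lines,
10 generations of intermating) genotyped at SNP markers, plus two
biological replicates of single-color expression intensities with planted
cis/trans effects and all three probe-artifact mechanisms (polymorphic
probes, a presence/absence region, hidden cross-hybridizing paralogs).

Writes map/genotypes/annotation/truth/expression TSVs under
results/simulated/.  Scale is kept desk-sized (1,200 probes, 500 markers)
so the whole analysis chain reruns in seconds.
"""
from pathlib import Path

from eqtlscan import io, simdata

OUT = Path("results/simulated")

CONFIG = simdata.SimConfig(
    n_lines=135,
    n_markers=500,
    n_probes=1200,
    n_cis_effects=300,
    n_trans_effects=100,
    frac_polymorphic_probes=0.05,
    pav_region=("chr6", 0.0, 25.0),
    n_crosshyb_probes=10,
    seed=2024,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = simdata.simulate_dataset(CONFIG, n_replicates=2)
    io.write_map(ds.gmap, OUT / "map.tsv")
    io.write_genotypes(ds.genotypes, OUT / "genotypes.tsv")
    io.write_annotation(ds.annotation, OUT / "annotation.tsv")
    simdata.write_truth(ds.truth, OUT / "truth.tsv")
    for k, expr in enumerate(ds.replicates, start=1):
        io.write_expression(expr, OUT / f"expression_rep{k}.tsv")

    truth = ds.truth
    n_eff = (truth["mode"] != "none").sum()
    print(f"simulated {truth['probe_id'].nunique()} probes x "
          f"{ds.genotypes.n_lines} lines, {ds.gmap.n_markers} markers")
    print(f"planted effects: {int(n_eff)} "
          f"({int((truth['mode'] == 'cis').sum())} cis, "
          f"{int((truth['mode'] == 'trans').sum())} trans)")
    print("artifacts:", truth.drop_duplicates("probe_id")["artifact"]
          .value_counts().to_dict())
    print(f"outputs under {OUT}/")


if __name__ == "__main__":
    main()
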