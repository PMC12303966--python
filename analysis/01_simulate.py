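"""Generate the study tables: soil properties and paired ASV communities.

Emulates the sampling design — three stand types (larch LF, mixed MF,
birch BF), seven 30 x 30 m plots per stand, two composite soil samples per
plot — drawing soil indicators around the published per-stand means/SDs
and microbial communities from the log-normal/multinomial model (fungal
communities carry a stand effect, bacterial communities do not).

Writes results/data/{soil_table,bacteria,fungi}.tsv.
"""

from pathlib import Path

from standnet import io, synthetic

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = synthetic.StandDesign(seed=SEED)
    soil = synthetic.generate_soil_table(design)
    bacteria, fungi = synthetic.generate_abundance_tables(design)

    io.write_soil_table(soil, OUT / "soil_table.tsv")
    io.write_abundance_table(bacteria, OUT / "bacteria.tsv")
    io.write_abundance_table(fungi, OUT / "fungi.tsv")

    print(f"design: {len(design.stand_labels)} stands x "
          f"{design.n_plots_per_stand} plots x {design.n_samples_per_plot} "
          f"samples = {design.n_samples} samples")
    print("per-stand soil means (drawn vs published):")
    for ind in ("SOC", "TN", "BD"):
        drawn = soil.groupby("stand")[ind].mean().round(2).to_dict()
        pub = {s: m for s, (m, _) in synthetic.TABLE2_SOIL_PARAMS[ind].items()}
        print(f"  {ind}: drawn {drawn} | published {pub}")
    print(f"bacteria: {bacteria.counts.shape[1]} ASVs, "
          f"fungi: {fungi.counts.shape[1]} ASVs, depth 10000")
    print(f"wrote tables to {OUT}/")


if __name__ == "__main__":
    main()
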