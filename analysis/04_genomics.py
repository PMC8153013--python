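"""Genomic divergence of the quadrants: TMB, spectra and interactions.

Computes mutations-per-megabase (38 Mb exome), per-subtype mutation
frequencies of the top recurrently mutated genes, pairwise
co-occurrence / exclusivity, and the TP53-mutation vs TIL-status
association.
"""

import argparse
from pathlib import Path

import pandas as pd

from timequad.genomics import (
    compute_tmb,
    interaction_table,
    mutation_frequency,
    mutation_group_association,
    mutation_matrix,
    somatic_interaction,
)
from timequad.io import read_maf
from timequad.survival import compare_groups


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--subtypes", type=Path, default=Path("results/subtypes.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    maf = read_maf(args.sim_dir / "muts.maf")
    sub = pd.read_csv(args.subtypes, sep="\t", index_col=0)
    samples = list(sub.index)

    tmb = compute_tmb(maf, samples)
    by_sub = tmb["tmb"].groupby(sub["subtype"], observed=True).mean()
    print("mean TMB (mut/Mb) per subtype:", by_sub.round(4).to_dict())
    kw = compare_groups(tmb["tmb"].values, sub["subtype"].values, kind="kruskal")
    print(f"TMB differs across subtypes: Kruskal-Wallis p = {kw.p_value:.3g}")

    mm = mutation_matrix(maf, samples)
    freq, altered = mutation_frequency(mm, sub["subtype"], top_k=min(10, mm.shape[1]))
    print("per-subtype mutation frequency (%):")
    print((100 * freq).round(1).to_string())
    print("altered rate (%) per subtype:", (100 * altered).round(1).to_dict())

    inter = interaction_table(somatic_interaction(mm, list(freq.index)))
    sig = inter[inter["p_value"] < 0.01]
    print(f"{len(sig)}/{len(inter)} gene pairs significant at p < 0.01")

    assoc = mutation_group_association(mm, "TP53", sub["til_pos"])
    print(f"TP53 mutation vs TIL status: {assoc['test']} p = {assoc['p_value']:.3g}; "
          f"mutated proportion per TIL group = {assoc['proportions']}")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    tmb.to_csv(args.out_dir / "tmb.tsv", sep="\t")
    freq.rename_axis("gene").to_csv(args.out_dir / "mutation_frequency.tsv", sep="\t")
    inter.to_csv(args.out_dir / "somatic_interaction.tsv", sep="\t", index=False)
    print(f"wrote genomics tables to {args.out_dir}")


if __name__ == "__main__":
    main()
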