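#!/usr/bin/env python
"""PCA of the complete modern panels with projection of the ancient samples.

Principal components are built from the diploid, essentially complete modern
outgroup panels; the low-coverage pseudo-haploid ancients are placed by
least-squares projection of their non-missing genotypes — the intermediate
position of the admixed farmer cohort between its two source lineages is the
qualitative pattern that motivates the formal modeling.
"""

import argparse
from pathlib import Path

from fstatkit.eigendata import read_eigenstrat
from fstatkit.pcaproj import fit_pca, project_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    prefix = args.out / "data" / "aaf_two_way"
    ds = read_eigenstrat(f"{prefix}.geno", f"{prefix}.snp", f"{prefix}.ind")

    modern = [i.individual_id for i in ds.individuals
              if i.population_label in ("Mbuti", "Han", "Onge")]
    ancient = [i.individual_id for i in ds.individuals
               if i.individual_id not in set(modern)]
    model = fit_pca(ds, modern, n_components=2)
    df = project_dataset(ds, model, modern + ancient, min_overlap=50)
    df["population"] = [i.rsplit("_", 1)[0] for i in df["individual_id"]]
    df.to_csv(args.out / "07_pca.tsv", sep="\t", index=False, float_format="%.6g")
    centroids = df.groupby("population")[["PC1", "PC2"]].mean().round(2)
    print("Population centroids on the modern PCs:")
    print(centroids.to_string())
    print(f"\nPer-individual coordinates written to {args.out / '07_pca.tsv'}")


if __name__ == "__main__":
    main()
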