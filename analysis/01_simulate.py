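"""Generate the synthetic screen dataset used by the downstream analyses.

Writes the gene-effect, dependency-probability and expression matrices plus
the lineage annotation and ground-truth manifest.  The matrices are large,
so they go under scratch/; the small manifests go under results/.
"""

import argparse
from pathlib import Path

from depscreen.simulate import SyntheticConfig, simulate_rnai_replicate, simulate_screen_dataset


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--scratch-dir", type=Path, default=Path("scratch/synthetic"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SyntheticConfig(seed=args.seed)
    eff, prob, expr, ann, truth = simulate_screen_dataset(cfg)
    rnai = simulate_rnai_replicate(eff, truth, cfg)

    args.scratch_dir.mkdir(parents=True, exist_ok=True)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    eff.data.to_csv(args.scratch_dir / "gene_effect_crispr.csv")
    prob.data.to_csv(args.scratch_dir / "dependency_probability.csv")
    expr.data.to_csv(args.scratch_dir / "expression_log2tpm1.csv")
    rnai.data.to_csv(args.scratch_dir / "gene_effect_rnai.csv")
    with open(args.out_dir / "lineage_annotation.tsv", "w") as fh:
        fh.write("line\tlineage\n")
        for line, lineage in ann.mapping.items():
            fh.write(f"{line}\t{lineage}\n")
    truth.to_frame().to_csv(args.out_dir / "ground_truth.tsv", sep="\t", index=False)

    sizes = ann.sizes()
    print(f"simulated {cfg.n_genes} genes x {cfg.n_lines} lines (seed {args.seed})")
    print(f"lineages: {sizes}")
    print(
        f"implanted {cfg.n_implants_per_lineage} lineage-specific dependencies "
        f"per lineage at effect {cfg.effect_implant}, noise sd {cfg.noise_sd}"
    )
    print(f"matrices -> {args.scratch_dir}/, manifests -> {args.out_dir}/")


if __name__ == "__main__":
    main()
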