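"""Run the one-vs-rest differential dependency screen and report the top
five targets per lineage.

Regenerates the seeded synthetic dataset in memory, screens every declared
lineage, writes the full ScreenRecord table, and checks the hits against
the implanted ground truth.
"""

import argparse
from pathlib import Path

from depscreen.io import write_records
from depscreen.screen import screen_all
from depscreen.simulate import SyntheticConfig, simulate_screen_dataset


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--k", type=int, default=5)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SyntheticConfig(seed=args.seed)
    eff, _, _, ann, truth = simulate_screen_dataset(cfg)
    ts = screen_all(eff, ann, k=args.k, lineages=[l for l, _ in cfg.lineages])

    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_records(ts.all_records(), args.out_dir / "screen_top_targets.tsv")

    n_exact = 0
    for lineage, _ in cfg.lineages:
        hits = ts.genes(lineage)
        implanted = set(truth.implanted_genes(lineage))
        n_exact += set(hits) == implanted
        best = ts.per_lineage[lineage][0]
        print(
            f"{lineage}: top gene {best.gene} (t = {best.t_statistic:.2f}, "
            f"p = {best.p_value:.2e}); top-{args.k} matches implants: "
            f"{set(hits) == implanted}"
        )
    print(
        f"{n_exact}/{len(cfg.lineages)} lineages recovered their implanted "
        f"dependencies exactly -> {args.out_dir / 'screen_top_targets.tsv'}"
    )


if __name__ == "__main__":
    main()
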