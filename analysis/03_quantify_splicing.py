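"""Quantify splicing and detect a planted differential cassette event.

Simulates a two-group cohort (20 vs 20 samples) from the synthetic locus
with a 0.4 delta-PSI shift planted on the exon-3 cassette, computes
junction PSI within shared-end clusters, tests every junction with the
Wilcoxon rank-sum test and Benjamini-Hochberg correction, and writes
results/psi.tsv and results/differential.tsv.
"""

import argparse
from pathlib import Path

from isoatlas.model import junctions_of
from isoatlas.quant import differential_events, differential_frame, psi_junction
from isoatlas.simulate import SpliceEvent, make_locus, simulate_junction_counts


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    locus = make_locus(
        events=[SpliceEvent("skip", (3,))],
        weights={"canonical": 0.5, "skip_ex3": 0.5},
        seed=args.seed,
    )
    groups = {f"s{i + 1}": ("A" if i < 20 else "B") for i in range(40)}
    matrix, _truth = simulate_junction_counts(
        locus, n_samples=40, groups=groups, group_psi_shift=0.4, seed=args.seed + 1
    )
    psi = psi_junction(matrix)
    events = differential_events(psi, groups)
    ranked = sorted(events, key=lambda e: (e.q_value, e.p_value))

    args.outdir.mkdir(parents=True, exist_ok=True)
    psi.psi.to_csv(args.outdir / "psi.tsv", sep="\t")
    differential_frame(ranked).to_csv(
        args.outdir / "differential.tsv", sep="\t", index=False
    )

    skip_keys = {
        j.key() for j in junctions_of(locus.transcript("skip_ex3"))
    } - {j.key() for j in junctions_of(locus.canonical)}
    top = ranked[0]
    print(f"tested {len(events)} junction events; top by q-value:")
    print(f"  event={top.event} delta_psi={top.delta_psi:+.3f} "
          f"p={top.p_value:.2e} q={top.q_value:.2e}")
    print("  planted skip junction ranked first:" , top.event in skip_keys)


if __name__ == "__main__":
    main()
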