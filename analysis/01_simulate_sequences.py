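#!/usr/bin/env python
"""Generate the synthetic marker panels and a query cohort.

Writes reference FASTA files (28S species references, COI haplogroup
references), query sequences for a mixed cohort of pure worms and
hybrids, and the generator's ground truth, under results/sequences/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import eisenia_hybrids as eh


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20180125)
    ap.add_argument("--outdir", type=Path, default=Path("results/sequences"))
    ap.add_argument("--n-individuals", type=int, default=50)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    outdir = args.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    panel = eh.generate_reference_panel(eh.SeqGenParams(), rng)
    eh.write_fasta(outdir / "refs_28s_A.fasta", panel.refs_28s_A)
    eh.write_fasta(outdir / "refs_28s_F.fasta", panel.refs_28s_F)
    for clade, refs in panel.coi_clades.items():
        eh.write_fasta(outdir / f"coi_{clade}.fasta", refs)

    # cohort proportions loosely follow the genotyped collection:
    # mostly pure worms, a minority of hybrids, a small f2 group
    labels = rng.choice(
        ["aAA", "fFF", "f2FF", "aAF", "fFA"],
        size=args.n_individuals,
        p=[0.40, 0.28, 0.06, 0.20, 0.06],
    )
    cohort = eh.generate_individuals(
        panel, [eh.GenotypeCode.from_label(l) for l in labels], rng
    )
    eh.write_fasta(outdir / "queries_coi.fasta", [c[2] for c in cohort])
    eh.write_fasta(outdir / "queries_28s.fasta", [c[3] for c in cohort])
    truth = {name: code.label for name, code, _, _ in cohort}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    mp = eh.MarkerPanel.build(panel.refs_28s_A, panel.refs_28s_F)
    (outdir / "panel.json").write_text(json.dumps(mp.to_dict(), indent=2) + "\n")
    d_af = eh.group_p_distance(panel.coi_clades["a"], panel.coi_clades["f"])
    d_ff2 = eh.group_p_distance(panel.coi_clades["f"], panel.coi_clades["f2"])
    print(
        f"panel: {len(mp.polymorphic_sites)} polymorphic / "
        f"{len(mp.diagnostic_sites)} diagnostic 28S sites; "
        f"COI divergences a-f {d_af:.3f}, f-f2 {d_ff2:.3f}; "
        f"{len(cohort)} query individuals -> {outdir}"
    )


if __name__ == "__main__":
    main()
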