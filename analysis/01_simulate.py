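"""Generate the synthetic study cohorts and write them to disk.

Writes the 50-complex main cohort and the 12-complex clustering cohort as
PDB files under scratch/ (bulky, regenerable) and their ground-truth
tables under results/.  Later scripts regenerate the same cohorts in
memory from the recorded seeds, so this step is for inspection and for
running the command-line pipeline on files.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, SCRATCH, cluster_cohort, main_cohort

from trpmhc.structures import write_pdb


def dump(pairs, truth, name):
    out = SCRATCH / "simulated" / name
    out.mkdir(parents=True, exist_ok=True)
    for st, ct in pairs:
        text = write_pdb(
            st,
            remarks=[
                f"trpmhc synthetic complex seed={ct.seed}",
                f"theta_true={ct.theta_true:.4f} pattern={ct.charge_pattern}",
            ],
        )
        (out / f"{st.id}.pdb").write_text(text)
    RESULTS.mkdir(exist_ok=True)
    truth.to_frame().to_csv(RESULTS / f"truth_{name}.tsv", sep="\t", index=False)
    print(f"{name}: {len(pairs)} complexes -> {out}, truth -> results/truth_{name}.tsv")


def main():
    dump(*main_cohort(), "main")
    dump(*cluster_cohort(), "cluster")


if __name__ == "__main__":
    main()
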