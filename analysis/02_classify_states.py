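"""Classify every simulated trajectory into A/D/T/U states.

Applies the default thresholds (closed: RMSD <= 2 A with zeta in
[-100, -50] deg; open: RMSD > 2 A with zeta in [50, 100] deg; transition:
open-like RMSD with closed-like zeta), annotates transition episodes, and
reports the frame agreement against the generator's ground truth.
"""

import argparse
from pathlib import Path

from pairswitch import classify_trajectory
from pairswitch.io import (
    load_generator_config,
    read_state_path,
    read_trajectory,
    write_labeled_trajectory,
    write_tsv,
)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run", default="scratch/run")
    args = parser.parse_args()

    run = Path(args.run)
    config = load_generator_config(run / "generator_config.yaml")
    for traj_path in sorted(run.glob("trajectory_T*.tsv")):
        tag = traj_path.stem.removeprefix("trajectory_")
        table = read_trajectory(traj_path)
        seq = classify_trajectory(table)
        write_labeled_trajectory(table, seq, run / f"states_{tag}.tsv")
        write_tsv(seq.episode_table(), run / f"episodes_{tag}.tsv")
        truth = read_state_path(run / f"truth_{tag}.tsv")
        agreement = (seq.labels == truth.frame_labels(config.frame_dt_ps)).mean()
        counts = seq.counts()
        print(
            f"{tag}: frame agreement with ground truth {agreement:.2%}; "
            f"label counts {counts}"
        )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
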