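"""Dwell-time and occupancy statistics per temperature.

Builds the per-state summary (mean lifetime, occupied probability,
number of occurrences), running-occupancy convergence curves and
lifetime histograms from the classified sequences, and writes them as
TSV tables under the run directory.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pairswitch import (
    cumulative_occupancy,
    lifetime_histogram,
    mean_lifetimes,
    occupancy,
    segment,
    transition_path_times,
)
from pairswitch.classify import StateSequence, annotate_episodes
from pairswitch.io import write_tsv


def load_sequence(path: Path) -> StateSequence:
    table = pd.read_csv(path, sep="\t")
    dt = float(np.median(np.diff(table["time_ps"])))
    return annotate_episodes(StateSequence(table["state"].to_numpy(), dt))


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run", default="scratch/run")
    parser.add_argument("--results", default="results")
    parser.add_argument("--n-boot", type=int, default=200)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    run = Path(args.run)
    results = Path(args.results)
    rows = []
    for states_path in sorted(run.glob("states_T*.tsv")):
        tag = states_path.stem.removeprefix("states_")
        T = float(tag.split("K")[0].lstrip("T"))
        seq = load_sequence(states_path)
        segs = segment(seq)
        occ = occupancy(segs, seq.total_time_ns)
        lifetimes = mean_lifetimes(segs, n_boot=args.n_boot, seed=args.seed)
        tpt = transition_path_times(segs, n_boot=args.n_boot, seed=args.seed)
        write_tsv(
            cumulative_occupancy(seq, stride=1000),
            results / f"occupancy_vs_time_{tag}.tsv",
        )
        hists = []
        for label in ("A", "D", "ata", "dtd"):
            try:
                counts, edges = lifetime_histogram(segs, label)
            except ValueError:
                continue
            hists.append(
                pd.DataFrame(
                    {
                        "label": label,
                        "bin_left_ns": edges[:-1],
                        "bin_right_ns": edges[1:],
                        "count": counts,
                    }
                )
            )
        write_tsv(pd.concat(hists, ignore_index=True), results / f"lifetime_histograms_{tag}.tsv")
        p = {"A": occ.p_a, "D": occ.p_d, "T": occ.p_t, "U": occ.p_u}
        for label in "ADT":
            stat = lifetimes.get(label)
            if stat is None:
                continue
            rows.append(
                {
                    "temperature_K": T,
                    "label": label,
                    "tau_ave_ns": stat.tau_ave_ns,
                    "p": p[label],
                    "N": stat.n,
                }
            )
        print(
            f"{tag}: p_a={occ.p_a:.3f} p_d={occ.p_d:.3f} p_t={occ.p_t:.3f}; "
            f"tau_a={lifetimes['A'].tau_ave_ns*1e3:.1f} ps "
            f"tau_d={lifetimes['D'].tau_ave_ns*1e3:.1f} ps; "
            f"t_tp(d->a)={tpt.t_tp_da_ns and round(tpt.t_tp_da_ns*1e3, 2)} ps "
            f"({tpt.n_da} crossings)"
        )
    summary = pd.DataFrame(rows)
    write_tsv(summary, results / "state_summary.tsv")
    print(f"wrote {results/'state_summary.tsv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
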