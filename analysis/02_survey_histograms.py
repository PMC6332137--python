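#!/usr/bin/env python
"""Tabulate the 10°-bin torsion histograms of the survey.

Bins follow the left-open/right-closed convention aligned to 0° (a value of
exactly 0 counts in the (−10, 0] bin); the two seam-straddling descriptors
are binned on the shifted (−360, 0] branch.  Writes results/histograms.tsv
and, when matplotlib is importable, per-descriptor bar plots under
results/figures/.
"""
from pathlib import Path

from mtpaconf import load_table1, summarize

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report = summarize(load_table1())

    lines = ["descriptor\tbin_gt\tbin_le\tcount"]
    for name, hist in report.histograms.items():
        for i, count in enumerate(hist.counts):
            lines.append(f"{name}\t{hist.edges[i]:g}\t{hist.edges[i+1]:g}"
                         f"\t{count}")
        peak = max(range(len(hist.counts)), key=hist.counts.__getitem__)
        print(f"{name:8s} modal bin ({hist.edges[peak]:g}, "
              f"{hist.edges[peak+1]:g}] with {hist.counts[peak]} "
              f"of {sum(hist.counts)}")
    (RESULTS / "histograms.tsv").write_text("\n".join(lines) + "\n")
    print(f"wrote {RESULTS / 'histograms.tsv'}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    figdir = RESULTS / "figures"
    figdir.mkdir(exist_ok=True)
    for name, hist in report.histograms.items():
        fig, ax = plt.subplots(figsize=(4, 2.5))
        centers = [(hist.edges[i] + hist.edges[i + 1]) / 2
                   for i in range(len(hist.counts))]
        ax.bar(centers, hist.counts, width=hist.bin_width * 0.9)
        ax.set_xlabel(f"{name} (deg)")
        ax.set_ylabel("frequency")
        fig.tight_layout()
        fig.savefig(figdir / f"{name}.svg")
        plt.close(fig)
    print(f"wrote figures under {figdir}")


if __name__ == "__main__":
    main()
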