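#!/usr/bin/env python
"""Generate the synthetic case-study scenario with known truth.

Writes the chromosome, the truth circle, the depth track and two long-read
sets — a "CO" condition where the circular element is abundant and a
"glucose" condition where it is absent — under results/simulation/.
"""

import argparse
from pathlib import Path

from megatx import io, pipelines

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=ROOT / "results" / "simulation")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    scenario = pipelines.default_scenario(args.seed)
    io.write_fasta(
        [(scenario.genome.name, scenario.genome.sequence)],
        args.outdir / "genome.fasta",
    )
    io.write_fasta(
        [(f"{scenario.circle.name} length={scenario.circle.length}",
          scenario.circle.sequence)],
        args.outdir / "circle.fasta",
    )
    scenario.track.to_bedgraph(args.outdir / "depth.bedgraph")
    for condition, weight in (("CO", pipelines.CIRCLE_WEIGHT), ("glucose", 0.0)):
        reads, truth = pipelines.scenario_reads(
            scenario, args.seed, circle_weight=weight
        )
        io.write_fastq(reads, args.outdir / f"reads_{condition}.fastq")
        print(
            f"{condition}: {len(reads)} reads, "
            f"{truth.total_template_bases:,} template bases "
            f"({truth.sources.get(scenario.circle.name, 0):,} from the circle)"
        )
    io.write_json(
        {
            "genome_length": scenario.genome.length,
            "dup1": [scenario.dup1.start, scenario.dup1.end],
            "dup2": [scenario.dup2.start, scenario.dup2.end],
            "circle_length": scenario.circle.length,
            "junctions": [
                {"name": j.name, "sequence": j.sequence, "flank_k": j.flank_k}
                for j in scenario.truth.junctions
            ],
        },
        args.outdir / "truth.json",
    )
    print(f"scenario (circle {scenario.circle.length:,} bp) written to {args.outdir}")


if __name__ == "__main__":
    main()
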