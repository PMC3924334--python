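"""One-call simulation study: simulate, index, align, call, evaluate.

Reproduces the evaluation design used throughout the package's tests: a
synthetic genome at GC 0.42, bisulfite reads at the default simulation
parameters (100-bp reads, 10x depth, 0.001->0.008 error ramp, 5% random
reads, mutation rate 0.002 with 20% indels, CpG methylation 20/75/5
unmethylated/full/partial), alignment with the default mapper settings
(k = 17, a = 0.90, up to 20 mapping locations, non-directional), and
dyad-merged methylation calling scored against the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import bs_simulator as sim
from . import methylation_caller as meth
from .mapper import HitSet, MapperConfig, map_reads, write_sam
from .reference_index import GenomeIndex, ReferenceGenome, build_index


@dataclass
class StudyResult:
    genome: ReferenceGenome
    index: GenomeIndex
    profile: sim.MethylationProfile
    reads: list[sim.SimulatedRead]
    hitsets: list[HitSet]
    sam_path: Path
    gmp_path: Path
    alignment_metrics: dict
    methylation_metrics: dict


def run_study(
    out_dir: str | Path,
    genome_length: int = 200_000,
    gc_fraction: float = 0.42,
    seed: int = 1,
    k: int = 17,
    workers: int = 1,
    tolerance: int = 5,
    params: sim.SimulationParams | None = None,
    config: MapperConfig | None = None,
) -> StudyResult:
    """Run the full simulate-align-call-evaluate pipeline in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_genome, s_meth, s_reads = [int(s) for s in ss.generate_state(3) % (2**31)]
    params = params or sim.SimulationParams()
    config = config or MapperConfig()

    genome = sim.simulate_genome(genome_length, gc_fraction, s_genome)
    profile = sim.assign_methylation(genome, params, s_meth)
    reads = sim.simulate_reads(genome, profile, params, s_reads)
    index = build_index(genome, k=k, step=1)

    from .prob_align import BisulfiteRead

    bs_reads = [BisulfiteRead(r.id, r.bases, r.quals) for r in reads]
    hitsets = map_reads(bs_reads, genome, index, config, workers=workers)

    sam_path = out_dir / "alignments.sam"
    write_sam(hitsets, genome, sam_path)

    table = meth.accumulate_evidence(hitsets, genome)
    dyads = meth.merge_cg_dyads(table, genome)
    gmp_path = out_dir / "methylome.gmp"
    meth.write_gmp(dyads, gmp_path)

    alignment_metrics = sim.evaluate_alignments(reads, sam_path, tolerance)
    methylation_metrics = sim.evaluate_methylation(
        dyads, profile.dyad_table(genome)
    )
    return StudyResult(
        genome=genome,
        index=index,
        profile=profile,
        reads=reads,
        hitsets=hitsets,
        sam_path=sam_path,
        gmp_path=gmp_path,
        alignment_metrics=alignment_metrics,
        methylation_metrics=methylation_metrics,
    )
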