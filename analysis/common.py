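"""Shared configuration for the numbered analysis scripts.

All scripts work on one deterministic synthetic study (seed 42, 40 genes,
10 planted targets) and write under results/study/. The simulation is
cheap and fully seeded, so each script re-derives the in-memory inputs it
needs instead of pickling state between steps; tables always go through
the TSVs on disk.
"""

from pathlib import Path

from tsrna_nrs.pipeline import PipelineConfig, stage_simulate

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"


def config(seed: int = 42) -> PipelineConfig:
    return PipelineConfig(seed=seed, outdir=str(RESULTS))


_bundle_cache = {}


def bundle(cfg: PipelineConfig):
    key = cfg.seed
    if key not in _bundle_cache:
        _bundle_cache[key] = stage_simulate(cfg)
    return _bundle_cache[key]
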