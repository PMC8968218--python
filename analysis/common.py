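"""Shared configuration for the numbered analysis drivers.

The drivers walk the full 12-construct synthetic survey (n = 6161, the
emulated study's sample size) through every pipeline stage, writing all
artifacts under results/analysis/.  Replicate counts and MCMC lengths are
moderated relative to the full-scale profile so a complete walkthrough
finishes in minutes on one CPU; the `full` profile preset mirrors the
published scale (5000 bootstraps, 10M iterations, 50,000 DAGs).
"""

from dissonet.config import RunConfig


def build_config(seed: int = 1, out_dir: str = "results/analysis") -> RunConfig:
    return RunConfig(
        master_seed=seed,
        profile="test",
        out_dir=out_dir,
        simulate={"n": 6161, "battery": "study", "missing_rate": 0.02},
        preprocess={"m": 2, "iterations": 3},
        ggm={"gamma": 0.5, "n_penalties": 100},
        boot={"B": 500, "case_drop_B": 40, "case_drop_fracs": [0.1, 0.3, 0.5, 0.7]},
        dag={"sampler": "partition", "iterations": 400_000, "target_samples": 5000},
        effects={"focus": ["dissociation", "cad"]},
    )


def parse_seed(description: str) -> int:
    import argparse

    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args().seed
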