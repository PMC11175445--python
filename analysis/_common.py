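"""Shared plumbing for the numbered analysis drivers."""

import argparse
from pathlib import Path

from mrmediate import SimulationConfig, read_sumstats, simulate_triplet, write_sumstats

REPO_ROOT = Path(__file__).resolve().parent.parent


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1, help="simulation seed")
    ap.add_argument("--results", type=Path, default=REPO_ROOT / "results",
                    help="results directory")
    return ap.parse_args()


def simulated_tables(results: Path, seed: int):
    """Load the simulated study, generating it first if 01 has not run."""
    sim_dir = results / "sim"
    paths = {name: sim_dir / f"{name}.tsv" for name in ("exposure", "mediator", "outcome")}
    if not all(p.is_file() for p in paths.values()):
        write_simulated(results, seed)
    return tuple(read_sumstats(paths[name], trait_name=name)
                 for name in ("exposure", "mediator", "outcome"))


def write_simulated(results: Path, seed: int):
    sim_dir = results / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)
    trip = simulate_triplet(cfg)
    for name, t in (("exposure", trip.exposure), ("mediator", trip.mediator),
                    ("outcome", trip.outcome)):
        write_sumstats(t, sim_dir / f"{name}.tsv")
    trip.truth.to_frame().to_csv(sim_dir / "ground_truth.tsv", sep="\t", index=False)
    return cfg, trip
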