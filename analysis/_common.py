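"""Shared setup for the analysis drivers: one head model, cached solves."""
import os
import sys

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
CACHE = os.path.join(os.path.dirname(__file__), "..", "scratch", "analysis_cache")


def get_solver(seed: int = 0):
    from ocufield.evaluation import ChannelSolver
    from ocufield.meshing import HeadGeometryParams, generate_layered_head
    from ocufield.pipeline import CachedChannelSolver
    from ocufield.tissues import default_conductivities

    mesh = generate_layered_head(HeadGeometryParams(seed=seed))
    return CachedChannelSolver(mesh, default_conductivities(),
                               cache_dir=CACHE)


def outdir() -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return RESULTS


def seed_from_argv(default: int = 0) -> int:
    for i, a in enumerate(sys.argv):
        if a == "--seed" and i + 1 < len(sys.argv):
            return int(sys.argv[i + 1])
    return default
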