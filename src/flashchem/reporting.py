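"""Result serialisation with provenance.

Every experiment directory carries a manifest with the configuration
hash and the seeds used, so re-running with the same configuration and
master seed reproduces the CSV curves byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import SimulationConfig
from .results import ExperimentResult


def write_reaction_log(reaction_log: list, path: str | Path) -> None:
    """Write a reaction log (from ``evolve``) as CSV.

    Columns: time_ps, channel_id, x_nm, y_nm, z_nm — one row per
    executed reaction, positions at the product placement point.
    """
    df = pd.DataFrame(reaction_log,
                      columns=["time_ps", "channel_id", "x_nm", "y_nm",
                               "z_nm"])
    df.to_csv(path, index=False, float_format="%.6g")


def write_results(results: ExperimentResult | list[ExperimentResult],
                  out_dir: str | Path,
                  config: SimulationConfig | None = None) -> dict:
    """Write JSON summaries + per-repeat G-curve CSVs + a manifest.

    Returns the manifest (also written as ``manifest.json``): config
    hash, seeds and the list of files produced.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(results, ExperimentResult):
        results = [results]
    files: list[str] = []
    summaries = []
    for si, res in enumerate(results):
        summaries.append(res.summary())
        for ri, curve in enumerate(res.curves):
            name = f"gcurve_s{si:02d}_r{ri:03d}.csv"
            curve.to_dataframe().to_csv(out / name, index=False,
                                        float_format="%.10g")
            files.append(name)
    if summaries:
        (out / "summary.json").write_text(json.dumps(summaries, indent=2))
        files.append("summary.json")
    manifest = {
        "config_sha256": config.config_hash() if config is not None else None,
        "master_seed": config.master_seed if config is not None else None,
        "seeds": [res.scenario.get("seed") for res in results],
        "scenarios": [res.scenario for res in results],
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
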