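"""Machine-readable report bundles.

A bundle is a directory of plain-text products (CSV/JSON) plus SVG plots,
with a ``manifest.json`` recording which pipeline stages ran, the seeds and
conventions used, and explicit markers for stages that were skipped.  All
products are byte-stable under a fixed seed and configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .layout import fruchterman_reingold, plot_case_drop, plot_centrality, plot_edge_ci, render_network

__all__ = ["export_report", "validate_bundle", "REQUIRED_FILES"]

STAGES = ("correlation", "network", "metrics", "stability", "comparison", "layout")
REQUIRED_FILES = ("manifest.json",)

CONVENTIONS = {
    "distance": "d_ij = 1 / |w_ij|",
    "closeness": "inverse of summed shortest-path distances over reachable nodes",
    "betweenness": "integer counts over one selected geodesic per pair "
    "(lexicographic tie-break from the smaller-indexed endpoint)",
    "zscore": "population standard deviation (ddof=0)",
}


def _float_fmt(x) -> float:
    return float(np.round(x, 12))


def export_report(
    outdir,
    network=None,
    correlation=None,
    centrality=None,
    edge_betw=None,
    path_lengths=None,
    edge_boot=None,
    case_drop=None,
    cs=None,
    nct_result=None,
    layout_coords=None,
    config: dict | None = None,
    seeds: dict | None = None,
    layout_seed: int = 0,
    log_lines: list[str] | None = None,
) -> Path:
    """Write every available pipeline product into *outdir* and return it.

    Stages not supplied are flagged as missing in the manifest rather than
    silently dropped.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    present: list[str] = []
    missing: list[str] = []

    if correlation is not None:
        present.append("correlation")
        correlation.to_csv(out / "correlation.csv")
        sidecar = {
            f"{a}|{b}": m for (a, b), m in sorted(correlation.method_per_pair.items())
        }
        _write_json(out / "correlation_methods.json", {
            "methods": sidecar,
            "psd_repaired": correlation.psd_repaired,
            "n": correlation.n,
        })
    else:
        missing.append("correlation")

    if network is not None:
        present.append("network")
        network.to_csv(out / "weights.csv")
        network.edge_list().to_csv(out / "edge_list.csv", index=False)
        _write_json(out / "network_manifest.json", {
            "lambda_selected": _float_fmt(network.lambda_selected),
            "ebic_gamma": network.ebic_gamma,
            "n": network.n,
            "n_edges": network.n_edges,
            "diagnostics": network.diagnostics,
        })
    else:
        missing.append("network")

    if centrality is not None or edge_betw is not None or path_lengths is not None:
        present.append("metrics")
        if centrality is not None:
            centrality.to_csv(out / "centrality.csv")
        if edge_betw is not None:
            edge_betw.to_csv(out / "edge_betweenness.csv")
        if path_lengths is not None:
            df = path_lengths.to_frame()
            df.index.name = "node"
            df.to_csv(out / "path_lengths.csv")
    else:
        missing.append("metrics")

    if edge_boot is not None or case_drop is not None:
        present.append("stability")
        if edge_boot is not None:
            edge_boot.to_csv(out / "edge_bootstrap.csv")
            plot_edge_ci(edge_boot, out / "fig_edge_ci.svg")
        if case_drop is not None:
            case_drop.to_csv(out / "case_drop.csv")
            plot_case_drop(case_drop, out / "fig_case_drop.svg")
        if cs is not None:
            _write_json(out / "cs_coefficient.json", cs.as_dict())
    else:
        missing.append("stability")

    if nct_result is not None:
        present.append("comparison")
        nct_result.to_json(out / "nct.json")
        nct_result.edge_table.to_csv(out / "nct_edges.csv", index=False)
    else:
        missing.append("comparison")

    if network is not None:
        present.append("layout")
        coords = layout_coords or fruchterman_reingold(network, seed=layout_seed)
        pd.DataFrame(coords.xy, index=coords.node_names, columns=["x", "y"]).to_csv(
            out / "layout.csv", index_label="node"
        )
        render_network(network, coords, out / "fig_network.svg", edge_ci=edge_boot)
        if centrality is not None:
            plot_centrality(centrality, out / "fig_centrality.svg")
    else:
        missing.append("layout")

    manifest = {
        "package_version": __version__,
        "stages_present": present,
        "stages_missing": missing,
        "conventions": CONVENTIONS,
        "seeds": seeds or {},
        "config": config or {},
    }
    _write_json(out / "manifest.json", manifest)
    if log_lines is not None:
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def validate_bundle(outdir) -> dict:
    """Check the bundle's structural contract; returns the parsed manifest.

    Raises ValueError when the manifest is missing/inconsistent or a
    present stage lacks its files.
    """
    out = Path(outdir)
    mpath = out / "manifest.json"
    if not mpath.exists():
        raise ValueError("bundle has no manifest.json")
    manifest = json.loads(mpath.read_text())
    for key in ("package_version", "stages_present", "stages_missing", "conventions", "seeds"):
        if key not in manifest:
            raise ValueError(f"manifest missing key {key!r}")
    required_by_stage = {
        "correlation": ["correlation.csv", "correlation_methods.json"],
        "network": ["weights.csv", "edge_list.csv", "network_manifest.json"],
        "metrics": ["centrality.csv"],
        "comparison": ["nct.json"],
        "layout": ["layout.csv", "fig_network.svg"],
    }
    for stage in manifest["stages_present"]:
        for fname in required_by_stage.get(stage, []):
            if not (out / fname).exists():
                raise ValueError(f"stage {stage!r} present but {fname} missing")
    both = set(manifest["stages_present"]) & set(manifest["stages_missing"])
    if both:
        raise ValueError(f"stages both present and missing: {both}")
    return manifest
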