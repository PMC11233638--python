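"""One-call orchestration of the full connectivity analysis.

Runs summary -> motif testing -> lobule clustering (and topography when
coordinates are supplied) on a connectivity table or the packaged canonical
dataset, and collects the results with a provenance block (package version,
seeds, config hash) so a report can be regenerated bit-for-bit.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

from . import __version__, defaults
from .clustering import hamming_matrix, to_newick, upgma, zone_concordance
from .connectivity import (
    ConnectivityDataset,
    build_fixture,
    dataset_summary,
    read_connectivity_table,
    zone_marginals,
)
from .motifs import motif_report
from .topography import read_coordinates, topography_report

log = logging.getLogger("cerebmotif")


@dataclass(frozen=True)
class AnalysisReport:
    summary: dict[str, Any]
    marginals: dict[str, Any]
    motifs: list[dict[str, Any]]
    newick: str
    zone_concordant: bool | None
    topography: list[dict[str, Any]] | None
    provenance: dict[str, Any]

    def payload(self) -> dict[str, Any]:
        """Deterministic content: everything except the timestamp."""
        d = asdict(self)
        d["provenance"] = {
            k: v for k, v in d["provenance"].items() if k != "timestamp"
        }
        return d

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _config_hash(config: dict[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_dataset(source: str | Path) -> ConnectivityDataset:
    """Load a connectivity table, or the packaged dataset for ``"fixture"``."""
    if str(source) == "fixture":
        return build_fixture()
    return read_connectivity_table(source)


def run_full_analysis(
    connectivity: str | Path = "fixture",
    coords: str | Path | None = None,
    config: dict[str, Any] | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Execute the full pipeline and (optionally) write report artifacts.

    ``config`` keys: ``family`` (motif pattern family), ``iterations``
    (bootstrap iterations).  Artifacts are written under
    ``out_dir/run-<config hash>/``.
    """
    config = dict(config or {})
    family = config.get("family", "nonempty")
    iterations = int(config.get("iterations", defaults.BOOTSTRAP_ITERATIONS))

    log.info("loading connectivity from %s", connectivity)
    ds = load_dataset(connectivity)
    summ = dataset_summary(ds)
    marg = zone_marginals(ds)

    log.info("motif testing (family=%s)", family)
    motifs = motif_report(ds, family=family)

    if ds.connected_cells():
        log.info("lobule clustering")
        tree = upgma(hamming_matrix(ds))
        newick = to_newick(tree)
        concordant = zone_concordance(tree).concordant
    else:
        log.warning("no connected cells: clustering skipped")
        newick = ""
        concordant = None

    topo_rows = None
    if coords is not None:
        log.info("topography bootstrap (%d iterations, seed %d)", iterations, seed)
        cc = read_coordinates(coords)
        topo = topography_report(cc, iterations=iterations, seed=seed)
        topo_rows = topo.to_frame().to_dict(orient="records")

    full_config = {
        "connectivity": str(connectivity),
        "coords": str(coords) if coords else None,
        "family": family,
        "iterations": iterations,
        "seed": seed,
    }
    report = AnalysisReport(
        summary={
            "n_total": summ.n_total,
            "n_connected": summ.n_connected,
            "lobule_histogram": summ.lobule_histogram,
            "zone_histogram": summ.zone_histogram,
        },
        marginals={
            "counts": {z.value: c for z, c in marg.counts.items()},
            "p_zone": {z.value: p for z, p in marg.p_zone.items()},
            "n_total": marg.n_total,
        },
        motifs=[
            {
                "pattern": m.label,
                "observed": m.observed,
                "expected": m.expected,
                "fold": m.fold,
                "direction": m.direction,
                "p_raw": m.p_raw,
                "p_adj": m.p_adj,
            }
            for m in motifs
        ],
        newick=newick,
        zone_concordant=concordant,
        topography=topo_rows,
        provenance={
            "package": "cerebmotif",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(full_config),
            "config": full_config,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    )

    if out_dir is not None:
        run_dir = Path(out_dir) / f"run-{report.provenance['config_hash']}"
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "report.json").write_text(report.to_json())
        (run_dir / "dendrogram.nwk").write_text(newick + "\n")
        (run_dir / "report.txt").write_text(render_text_report(report))
        log.info("report written to %s", run_dir)
    return report


def render_text_report(report: AnalysisReport) -> str:
    lines = [
        "cerebmotif analysis report",
        "==========================",
        f"cells tested: {report.summary['n_total']} "
        f"({report.summary['n_connected']} with >= 1 connected lobule)",
        f"zone counts: {report.marginals['counts']}",
        "",
        f"{'pattern':<42}{'obs':>4}{'exp':>8}{'fold':>8}{'p_adj':>10}",
    ]
    for m in report.motifs:
        fold = f"{m['fold']:.2f}" if m["fold"] is not None else "-"
        lines.append(
            f"{m['pattern']:<42}{m['observed']:>4}{m['expected']:>8.3f}"
            f"{fold:>8}{m['p_adj']:>10.4f}"
        )
    lines += ["", f"lobule dendrogram: {report.newick}",
              f"within-zone clades merge first: {report.zone_concordant}"]
    if report.topography:
        lines += ["", f"{'group':>5}{'plane':>8}{'n':>4}{'r2':>8}{'p_boot':>9}"]
        for r in report.topography:
            lines.append(
                f"{r['group']:>5}{r['plane']:>8}{r['n']:>4}{r['r2']:>8.3f}{r['p_boot']:>9.4f}"
            )
    return "\n".join(lines) + "\n"
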