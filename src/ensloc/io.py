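"""Readers/writers for the pipeline's table formats, and the pipeline driver.

The single-cell export mirrors the download format of localization
databases: one row per segmented cell with columns

    Object ID, X-coordinate, Y-coordinate, GFP Intensity (Ig), Localization

where the intensity is the per-cell integrated-GFP / area ratio and the
localization field is a semicolon-joined list of class labels, or one of
``unclassified`` / ``dead`` / ``ghost``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .ensemble import AssignmentVector
from .segment import GFP, CellRegion, Micrograph

SINGLE_CELL_HEADER = (
    "Object ID",
    "X-coordinate",
    "Y-coordinate",
    "GFP Intensity (Ig)",
    "Localization",
)


@dataclass(frozen=True)
class SingleCellRow:
    object_id: int
    x: float
    y: float
    gfp_intensity: float
    localization: str


def _localization_field(assignment: AssignmentVector) -> str:
    if assignment.qc != "pass":
        return assignment.qc
    labels = assignment.assigned_classes()
    return ";".join(labels) if labels else "unclassified"


def write_single_cell_table(
    cells: list[tuple[CellRegion, AssignmentVector]],
    path: str | Path,
) -> Path:
    """Write the single-cell table, ordered by object id."""
    path = Path(path)
    rows = []
    for region, assignment in cells:
        if GFP not in region.integrated_intensity:
            raise ValueError(f"cell {region.object_id} lacks a GFP measurement")
        rows.append(
            SingleCellRow(
                object_id=region.object_id,
                x=region.centroid[0],
                y=region.centroid[1],
                gfp_intensity=region.integrated_intensity[GFP] / region.area,
                localization=_localization_field(assignment),
            )
        )
    rows.sort(key=lambda r: r.object_id)
    with open(path, "w") as fh:
        fh.write("\t".join(SINGLE_CELL_HEADER) + "\n")
        for r in rows:
            fh.write(
                f"{r.object_id}\t{r.x:.2f}\t{r.y:.2f}\t{r.gfp_intensity:.4f}\t{r.localization}\n"
            )
    return path


def read_single_cell_table(path: str | Path) -> list[SingleCellRow]:
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != SINGLE_CELL_HEADER:
        raise ValueError(f"{path} is not a single-cell table")
    rows = []
    for line in lines[1:]:
        oid, x, y, ig, loc = line.split("\t")
        rows.append(SingleCellRow(int(oid), float(x), float(y), float(ig), loc))
    return rows


def read_micrograph_tiff(path: str | Path, channel: str, **ids) -> Micrograph:
    import tifffile

    return Micrograph(tifffile.imread(path).astype(np.float64), channel, **ids)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def table_header_comment(cfg_hash: str) -> str:
    return f"# ensloc {__version__} config_hash={cfg_hash}\n"


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute segment -> features -> ensemble -> score on phantom screens.

    ``config`` (typically loaded from YAML) names the screens to
    simulate, the training scale, and a master seed::

        seed: 1
        train: {n_per_pool: 120}
        screens:
          - {screen_id: WT, n_fields: 2, n_cells: 60,
             class_mix: {cytoplasm: 1.0}, dead_fraction: 0.02}
        comparisons:           # optional, condition vs control screen ids
          - {condition: RAP, control: WT}

    Outputs per screen: single-cell tables, assignment tables, a
    localization profile and abundance record; per comparison: a z-LOC /
    dPL table.  A run manifest records seeds, registry and config hashes,
    so a rerun with the same config is byte-identical.
    """
    from . import ensemble as E
    from . import features as F
    from . import phantom as P
    from . import score as S
    from . import segment as G

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    registry = F.default_registry()
    cfg_hash = config_hash(config)
    header = table_header_comment(cfg_hash)

    train_cfg = config.get("train", {})
    graph = E.train_phantom_ensemble(
        n_per_pool=int(train_cfg.get("n_per_pool", 120)),
        seed=seed,
        n_bags=int(train_cfg.get("n_bags", 25)),
    )

    profiles: dict[str, S.LocalizationProfile] = {}
    abundances: dict[str, S.AbundanceRecord] = {}
    for si, screen in enumerate(config.get("screens", [])):
        screen_id = screen["screen_id"]
        all_assignments: list[AssignmentVector] = []
        all_cells: list[CellRegion] = []
        for fi in range(int(screen.get("n_fields", 1))):
            spec = P.PhantomSpec(
                n_cells=int(screen.get("n_cells", 60)),
                class_mix=dict(screen.get("class_mix", {"cytoplasm": 1.0})),
                dead_fraction=float(screen.get("dead_fraction", 0.0)),
                ghost_fraction=float(screen.get("ghost_fraction", 0.0)),
                budded_fraction=float(screen.get("budded_fraction", 0.35)),
                expression_mean=float(screen.get("expression_mean", 100.0)),
                seed=seed + 1000 * (si + 1) + fi,
            )
            rfp, gfp, _truth = P.generate_micrograph(spec)
            rfp.screen_id = gfp.screen_id = screen_id
            rfp.field_index = gfp.field_index = fi
            regions = G.segment_cells(rfp)
            vectors = []
            kept_regions = []
            for r in regions:
                G.measure_region(r, gfp)
                fv = F.extract_features(r, gfp, rfp, registry)
                if fv.extractable:
                    vectors.append(fv)
                    kept_regions.append(r)
            if not vectors:
                continue
            X, rh = F.feature_matrix(vectors)
            assignments = E.classify_cells(
                graph, X, [v.cell_ref for v in vectors], registry_hash=rh
            )
            write_single_cell_table(
                list(zip(kept_regions, assignments)),
                out / f"{screen_id}_field{fi}_cells.tsv",
            )
            all_assignments.extend(assignments)
            all_cells.extend(kept_regions)
        if not all_assignments:
            raise RuntimeError(f"screen {screen_id}: no cells survived extraction")
        E.write_assignments(out / f"{screen_id}_assignments.tsv", all_assignments)
        profiles[screen_id] = S.loc_profile(
            all_assignments, protein_id=screen.get("protein_id", screen_id), screen_id=screen_id
        )
        abundances[screen_id] = S.abundance_ig(
            all_cells, screen.get("protein_id", screen_id), screen_id, all_assignments
        )

    with open(out / "profiles.tsv", "w") as fh:
        fh.write(header)
        fh.write("screen_id\tn_cells\tn_classifiable\tIg\t" + "\t".join(P.CLASSES) + "\n")
        for sid, prof in profiles.items():
            ig = abundances[sid].ig
            fh.write(
                f"{sid}\t{prof.n_cells_total}\t{prof.n_classifiable}\t"
                f"{ig:.4f}\t" + "\t".join(f"{s:.4f}" for s in prof.loc_scores) + "\n"
            )

    comparisons = config.get("comparisons", [])
    if comparisons:
        with open(out / "comparisons.tsv", "w") as fh:
            fh.write(header)
            fh.write("condition\tcontrol\tdPL\t" + "\t".join(f"zLOC_{c}" for c in P.CLASSES) + "\n")
            for comp in comparisons:
                rec = S.compare_profiles(
                    profiles[comp["condition"]],
                    profiles[comp["control"]],
                    abundances[comp["condition"]],
                    abundances[comp["control"]],
                )
                fh.write(
                    f"{comp['condition']}\t{comp['control']}\t{rec.dpl:.4f}\t"
                    + "\t".join(f"{z:.4f}" for z in rec.zloc)
                    + "\n"
                )

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "registry_hash": registry.hash,
        "config_hash": cfg_hash,
        "config": config,
        "screens": sorted(profiles),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
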