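"""End-to-end pipeline driver with a serialisable run configuration.

A :class:`RunConfig` (one YAML file, versioned schema) fixes every parameter
and seed of a run; :func:`run_pipeline` chains the stages

    simulate counts → simulate FASTQ → demux → normalize → differential model
    → screen simulation → PCA → decile contrast → probe sets → enrichment →
    profiles

and writes a provenance manifest (package version, seeds, SHA-256 of every
input and output).  A run re-executed from its saved config reproduces all
outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demux import count_umis, write_report
from .diffmodel import ModelSpec, differential_table
from .io import write_layout, write_panel, write_plate_map
from .normalize import size_factors
from .readmodel import ReadLayout
from .screen import (
    annotate_pcs,
    assign_probe_sets,
    decile_contrast,
    enrichment_table,
    gsea,
    kinase_profiles,
    profile_cluster_compare,
    screen_pca,
)
from .synth import (
    random_panel,
    random_plate,
    simulate_counts,
    simulate_fastq,
    simulate_screen,
    write_fastq,
)

SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict = {
    "version": SCHEMA_VERSION,
    "seed": 0,
    "layout": {},
    "tolerance": 1,
    "simulate": {
        "n_antibodies": 40,
        "n_wells": 24,
        "dispersion": 0.2,
        "depth_range": [0.7, 1.4],
        "base_mean_range": [50.0, 300.0],
        "duplication_rate": 0.012,
        "barcode_error_rate": 0.002,
        "n_up": 13,
        "n_down": 7,
        "effect_size": 0.9,
    },
    "model": {
        "treatment": "treatment",
        "reference": "control",
        "blocking": ["replicate", "batch"],
        "dispersion": "ml",
    },
    "screen": {
        "n_probes": 294,
        "n_phenotypes": 70,
        "n_kinases": 225,
        "n_true_kinases": 13,
        "members_per_kinase": 14,
        "axis_strength": 12.0,
        "n_active_probes": 18,
        "noise_sd": 1.0,
        "k": 4,
        "fraction": 0.10,
        "alpha": 0.01,
        "fdr": 0.01,
        "n_perm": 10000,
        "k_clusters": 4,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Validated, fully serialisable pipeline configuration."""

    data: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG))

    def __post_init__(self) -> None:
        self.data = _merge(DEFAULT_CONFIG, self.data)
        if self.data.get("version") != SCHEMA_VERSION:
            raise ValueError(
                f"config schema version {self.data.get('version')!r} not supported "
                f"(expected {SCHEMA_VERSION})"
            )
        if not isinstance(self.data.get("seed"), int):
            raise ValueError("config requires an integer 'seed'")

    def __getitem__(self, key: str):
        return self.data[key]

    @property
    def seed(self) -> int:
        return self.data["seed"]

    @property
    def layout(self) -> ReadLayout:
        return ReadLayout.from_dict(self.data.get("layout") or {})

    def model_spec(self) -> ModelSpec:
        m = self.data["model"]
        return ModelSpec(
            treatment=m["treatment"],
            reference=m.get("reference"),
            blocking=tuple(m.get("blocking", ())),
            dispersion=m.get("dispersion", "ml"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig | dict | str | Path, outdir) -> Path:
    """Execute every stage under ``outdir`` and write a provenance manifest.

    Returns the output directory.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    rng_seeds = {
        "panel": seed,
        "plate": seed + 1,
        "counts": seed + 2,
        "fastq": seed + 3,
        "screen": seed + 4,
        "gsea": seed + 5,
        "kmeans": seed + 6,
    }
    sim = config["simulate"]
    scr = config["screen"]
    outputs: list[Path] = []

    def _write(path: Path):
        outputs.append(path)
        return path

    # --- stage: inputs (panel / plate / layout) ------------------------------
    try:
        layout = config.layout
        panel = random_panel(sim["n_antibodies"], layout.bc1_len, seed=rng_seeds["panel"])
        plate = random_plate(sim["n_wells"], layout.bc2_len, seed=rng_seeds["plate"])
        write_panel(panel, _write(outdir / "panel.tsv"))
        write_plate_map(plate, _write(outdir / "plate_map.csv"))
        write_layout(layout, _write(outdir / "layout.yaml"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", exc) from exc

    # --- stage: simulate (ground-truth counts realised as reads) -------------
    try:
        n_ab = sim["n_antibodies"]
        rng = np.random.default_rng(rng_seeds["counts"])
        beta = np.zeros(n_ab)
        hot = rng.permutation(n_ab)[: sim["n_up"] + sim["n_down"]]
        beta[hot[: sim["n_up"]]] = sim["effect_size"]
        beta[hot[sim["n_up"] :]] = -sim["effect_size"]
        truth_counts, counts_truth = simulate_counts(
            plate,
            n_antibodies=n_ab,
            effects=beta,
            dispersion=sim["dispersion"],
            depth_range=tuple(sim["depth_range"]),
            base_mean_range=tuple(sim["base_mean_range"]),
            reference=config["model"].get("reference"),
            seed=rng_seeds["counts"],
        )
        counts_truth.to_json(_write(outdir / "counts.truth.json"))
        reads, fastq_truth = simulate_fastq(
            panel,
            plate,
            layout,
            truth_counts.counts,
            duplication_rate=sim["duplication_rate"],
            barcode_error_rate=sim["barcode_error_rate"],
            seed=rng_seeds["fastq"],
        )
        write_fastq(reads, _write(outdir / "reads.fastq"))
        fastq_truth.to_json(_write(outdir / "reads.fastq.truth.json"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    # --- stage: demux --------------------------------------------------------
    try:
        matrix = count_umis(
            outdir / "reads.fastq", layout, panel, plate, tolerance=config["tolerance"]
        )
        matrix.to_tsv(_write(outdir / "counts.tsv"))
        write_report(matrix, _write(outdir / "demux_report.json"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("demux", exc) from exc

    # --- stage: normalize ----------------------------------------------------
    try:
        factors = size_factors(matrix)
        factors.to_tsv(_write(outdir / "size_factors.tsv"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("normalize", exc) from exc

    # --- stage: diff ---------------------------------------------------------
    try:
        spec = config.model_spec()
        diff = differential_table(matrix, spec, factors, plate_df=plate.wells)
        diff.to_tsv(_write(outdir / "diff_results.tsv"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("diff", exc) from exc

    # --- stage: screen -------------------------------------------------------
    try:
        smat, inhibition, screen_truth = simulate_screen(
            n_probes=scr["n_probes"],
            n_phenotypes=scr["n_phenotypes"],
            n_kinases=scr["n_kinases"],
            n_true_kinases=scr["n_true_kinases"],
            members_per_kinase=scr["members_per_kinase"],
            n_active_probes=scr["n_active_probes"],
            axis_strength=scr["axis_strength"],
            noise_sd=scr["noise_sd"],
            seed=rng_seeds["screen"],
        )
        smat.values.rename_axis("probe_id").to_csv(_write(outdir / "screen_matrix.tsv"), sep="\t")
        inhibition.rename_axis("probe_id").to_csv(_write(outdir / "inhibition.csv"))
        screen_truth.to_json(_write(outdir / "screen.truth.json"))

        pca = screen_pca(smat, k=scr["k"])
        pca.scores.rename_axis("probe_id").to_csv(_write(outdir / "pca_scores.tsv"), sep="\t")
        pca.loadings.rename_axis("phenotype").to_csv(_write(outdir / "pca_loadings.tsv"), sep="\t")
        pd.Series(
            pca.variance_explained, index=pca.scores.columns, name="variance_explained"
        ).rename_axis("component").to_csv(_write(outdir / "pca_variance.tsv"), sep="\t")
        corr, order = annotate_pcs(smat, pca)
        corr.rename_axis("phenotype").to_csv(_write(outdir / "pc_annotation.tsv"), sep="\t")

        diff_pc = _differentiation_pc(pca, screen_truth)
        contrast = decile_contrast(
            smat,
            pca.scores[diff_pc],
            fraction=scr["fraction"],
            alpha=scr["alpha"],
            fdr=scr["fdr"],
        )
        contrast.to_csv(_write(outdir / "decile_contrast.tsv"), sep="\t", index=False)

        sets = assign_probe_sets(inhibition, alpha=scr["alpha"])
        pd.DataFrame(
            dict(
                kinase=[ps.kinase for ps in sets],
                n_members=[len(ps) for ps in sets],
                members=[",".join(ps.members) for ps in sets],
            )
        ).to_csv(_write(outdir / "probe_sets.tsv"), sep="\t", index=False)

        enr = gsea(
            pca.scores[diff_pc],
            [ps for ps in sets if len(ps) >= 3],
            n_perm=scr["n_perm"],
            seed=rng_seeds["gsea"],
        )
        enrichment_table(enr).to_csv(_write(outdir / "enrichment.tsv"), sep="\t", index=False)

        hit_sets = [
            ps
            for ps in sets
            if any(r.kinase == ps.kinase and r.p_value < scr["alpha"] and r.q_value < scr["fdr"] for r in enr)
        ]
        if len(hit_sets) > scr["k_clusters"]:
            profiles, sems = kinase_profiles(smat.values, hit_sets)
            profiles.rename_axis("kinase").to_csv(_write(outdir / "profiles_mean.tsv"), sep="\t")
            sems.rename_axis("kinase").to_csv(_write(outdir / "profiles_sem.tsv"), sep="\t")
            top = enrichment_table(enr).sort_values(["p_value", "kinase"]).iloc[0]["kinase"]
            labels, pvals = profile_cluster_compare(
                profiles,
                smat.values,
                hit_sets,
                reference_kinase=str(top),
                k_clusters=scr["k_clusters"],
                seed=rng_seeds["kmeans"],
            )
            labels.rename("cluster").rename_axis("kinase").to_csv(
                _write(outdir / "profile_clusters.tsv"), sep="\t"
            )
            pvals.rename_axis("kinase").to_csv(_write(outdir / "profile_vs_reference_p.tsv"), sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise StageError("screen", exc) from exc

    # --- manifest ------------------------------------------------------------
    config.to_yaml(outdir / "run_config.yaml")
    manifest = {
        "package": "idseq",
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "stage_seeds": rng_seeds,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        "config_sha256": _sha256(outdir / "run_config.yaml"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _differentiation_pc(pca, screen_truth) -> str:
    """Pick the PC most correlated with the planted differentiation axis."""
    axes = np.asarray(screen_truth.truth["axes"], dtype=float)
    diff_axis = int(screen_truth.truth["differentiation_axis"])
    target = axes[diff_axis]
    corrs = [
        abs(float(np.corrcoef(pca.loadings[pc].to_numpy(), target)[0, 1]))
        for pc in pca.loadings.columns
    ]
    return str(pca.loadings.columns[int(np.argmax(corrs))])


def verify_manifest(outdir) -> bool:
    """Re-hash every recorded output; True iff all hashes match."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, digest in manifest["outputs"].items():
        if _sha256(outdir / name) != digest:
            return False
    return True
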