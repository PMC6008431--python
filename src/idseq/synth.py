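"""Ground-truthed generators for every pipeline stage.

Three generators emulate the data the assay produces, each returning its
ground truth alongside the data so recovery can be scored exactly:

* :func:`simulate_fastq` — triple-barcoded reads with PCR duplication
  (geometric re-sampling of each molecule) and per-base substitution errors
  on the barcode segments;
* :func:`simulate_counts` — NB-distributed antibody × well count matrices
  with planted treatment effects and log-uniform well depths;
* :func:`simulate_screen` — a probes × phenotypes signed-p matrix as planted
  low-rank axes plus noise, with a matching probes × kinases %-inhibition
  matrix carrying planted inhibitory members per kinase.

All generators are pure functions of (parameters, seed).  Default scales
mirror the assay geometry: a 70-antibody panel read out across 384-well
plates, and a screen of ~300 probes against 225 kinases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demux import UMICountMatrix
from .readmodel import AntibodyPanel, PlateMap, ReadLayout
from .screen import ScreenMatrix

BASES = np.array(list("ACGT"))

#: UMI duplicate rate observed in high-quality runs; the generator default
DEFAULT_DUPLICATION = 0.012


@dataclass
class TruthRecord:
    """Ground truth serialized next to every generated dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"kind": self.kind, "seed": self.seed, "params": self.params, "truth": self.truth},
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TruthRecord":
        text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
        d = json.loads(text)
        return cls(kind=d["kind"], seed=d["seed"], params=d["params"], truth=d["truth"])


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return {"index": list(obj.index), "columns": list(obj.columns), "data": obj.to_numpy().tolist()}
    if isinstance(obj, pd.Series):
        return {"index": list(obj.index), "data": obj.to_numpy().tolist()}
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _random_barcodes(rng: np.random.Generator, n: int, length: int, min_dist: int = 3) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_dist (rejection
    sampling; fine for the panel sizes used here)."""
    codes: list[np.ndarray] = []
    attempts = 0
    while len(codes) < n:
        cand = rng.integers(0, 4, size=length)
        if all(int(np.sum(cand != c)) >= min_dist for c in codes):
            codes.append(cand)
        attempts += 1
        if attempts > 200 * n + 10000:
            raise RuntimeError(
                f"could not place {n} barcodes of length {length} at distance {min_dist}"
            )
    return ["".join(BASES[c]) for c in codes]


def random_panel(
    n_antibodies: int = 70,
    bc_len: int = 10,
    seed: int = 0,
    n_spike_in: int = 0,
) -> AntibodyPanel:
    """A distance-validated random antibody panel (plus optional spike-ins)."""
    rng = np.random.default_rng(seed)
    total = n_antibodies + n_spike_in
    codes = _random_barcodes(rng, total, bc_len)
    ids = [f"Ab{i + 1:03d}" for i in range(n_antibodies)] + [
        f"spike{i + 1:02d}" for i in range(n_spike_in)
    ]
    return AntibodyPanel(
        entries=dict(zip(ids, codes)), spike_in=set(ids[n_antibodies:])
    )


def random_plate(
    n_wells: int = 96,
    bc_len: int = 10,
    seed: int = 1,
    treatments: tuple[str, ...] = ("control", "treated"),
    n_replicates: int = 2,
    n_batches: int = 1,
) -> PlateMap:
    """A random plate map with balanced treatment/replicate/batch labels."""
    rng = np.random.default_rng(seed)
    codes = _random_barcodes(rng, n_wells, bc_len)
    ids = [f"W{i + 1:03d}" for i in range(n_wells)]
    df = pd.DataFrame(
        {
            "barcode": codes,
            "treatment": [treatments[i % len(treatments)] for i in range(n_wells)],
            "replicate": [f"r{(i // len(treatments)) % n_replicates + 1}" for i in range(n_wells)],
            "batch": [f"b{i % n_batches + 1}" for i in range(n_wells)],
        },
        index=pd.Index(ids, name="well_id"),
    )
    return PlateMap(wells=df)


def _mutate_segment(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < error_rate
    if not hit.any():
        return seq
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_fastq(
    panel: AntibodyPanel,
    plate: PlateMap,
    layout: ReadLayout,
    truth_counts: pd.DataFrame,
    duplication_rate: float = DEFAULT_DUPLICATION,
    barcode_error_rate: float = 0.0,
    seed: int = 0,
    out_path=None,
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Reads realising ``truth_counts`` distinct molecules per (antibody, well).

    Each molecule gets a distinct random UMI and is emitted Geometric(1 - d)
    times (support >= 1), so the expected duplicate fraction equals
    ``duplication_rate``.  Substitution errors at ``barcode_error_rate`` per
    base are applied to the two barcode segments only.  Output order is
    shuffled.  Returns (records, truth); records are (name, sequence) pairs,
    also written as FASTQ when ``out_path`` is given.
    """
    if not 0 <= duplication_rate < 1:
        raise ValueError("duplication_rate must be in [0, 1)")
    if not 0 <= barcode_error_rate < 1:
        raise ValueError("barcode_error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    truth_counts = truth_counts.loc[
        [a for a in panel.ids if a in truth_counts.index],
        [w for w in plate.ids if w in truth_counts.columns],
    ]
    umi_space = 4 ** layout.umi_len
    if int(truth_counts.to_numpy().max(initial=0)) > umi_space:
        raise ValueError("truth count exceeds the UMI sequence space")
    ab_codes = panel.barcodes
    well_codes = plate.barcodes
    reads: list[tuple[str, str]] = []
    ridx = 0
    for ab in truth_counts.index:
        for well in truth_counts.columns:
            n_mol = int(truth_counts.at[ab, well])
            if n_mol == 0:
                continue
            umis = set()
            while len(umis) < n_mol:
                draw = rng.integers(0, 4, size=(n_mol - len(umis), layout.umi_len))
                for row in draw:
                    umis.add("".join(BASES[row]))
                    if len(umis) == n_mol:
                        break
            copies = (
                rng.geometric(1.0 - duplication_rate, size=n_mol)
                if duplication_rate > 0
                else np.ones(n_mol, dtype=int)
            )
            for umi, k in zip(sorted(umis), copies):
                for _ in range(int(k)):
                    bc1 = _mutate_segment(ab_codes[ab], rng, barcode_error_rate)
                    bc2 = _mutate_segment(well_codes[well], rng, barcode_error_rate)
                    parts = {
                        "UMI": umi,
                        "ANCHOR": layout.anchor,
                        "BC1": bc1,
                        "BC2": bc2,
                    }
                    seq = "".join(parts[t] for t in layout.segment_order)
                    reads.append((f"read{ridx}", seq))
                    ridx += 1
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    truth = TruthRecord(
        kind="fastq",
        seed=seed,
        params=dict(
            duplication_rate=duplication_rate,
            barcode_error_rate=barcode_error_rate,
            layout=layout.to_dict(),
            n_reads=len(reads),
        ),
        truth=dict(counts=truth_counts),
    )
    if out_path is not None:
        write_fastq(reads, out_path)
        truth.to_json(str(out_path) + ".truth.json")
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB2 draws at the given means: Var = mean + dispersion * mean^2."""
    r = 1.0 / dispersion
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p)


def simulate_counts(
    plate: PlateMap,
    n_antibodies: int = 70,
    effects: np.ndarray | dict | None = None,
    dispersion: float = 0.2,
    depth_range: tuple[float, float] = (0.5, 2.0),
    base_mean_range: tuple[float, float] = (100.0, 5000.0),
    treatment: str = "treatment",
    reference: str | None = None,
    seed: int = 0,
) -> tuple[UMICountMatrix, TruthRecord]:
    """Antibody × well NB counts with planted treatment log fold changes.

    counts[a, w] ~ NB(mean = s_w * mu_a * exp(x_w * beta_a), dispersion) with
    size factors s_w log-uniform over ``depth_range`` and x_w the indicator of
    the non-reference treatment level.  ``effects`` maps antibody index (or a
    full vector) to beta on the natural-log scale; default all zero.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    wells = plate.ids
    tr = plate.covariate(treatment).astype(str)
    levels = sorted(tr.unique())
    ref = reference if reference is not None else levels[0]
    x = (tr != ref).to_numpy().astype(float)

    beta = np.zeros(n_antibodies)
    if effects is not None:
        if isinstance(effects, dict):
            for idx, val in effects.items():
                beta[int(idx)] = float(val)
        else:
            beta = np.asarray(effects, dtype=float)
            if beta.shape != (n_antibodies,):
                raise ValueError("effects vector must have one entry per antibody")

    lo, hi = depth_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(wells)))
    mu0 = np.exp(rng.uniform(*np.log(base_mean_range), size=n_antibodies))
    mean = s[None, :] * mu0[:, None] * np.exp(beta[:, None] * x[None, :])
    counts = nb_draws(rng, mean, dispersion)
    ab_ids = [f"Ab{i + 1:03d}" for i in range(n_antibodies)]
    matrix = pd.DataFrame(counts, index=ab_ids, columns=wells)
    total = int(matrix.to_numpy().sum())
    umat = UMICountMatrix(counts=matrix, reads_total=total, reads_assigned=total)
    truth = TruthRecord(
        kind="counts",
        seed=seed,
        params=dict(
            n_antibodies=n_antibodies,
            dispersion=dispersion,
            depth_range=list(depth_range),
            base_mean_range=list(base_mean_range),
            treatment=treatment,
            reference=ref,
        ),
        truth=dict(
            beta=dict(zip(ab_ids, beta)),
            size_factors=dict(zip(wells, s)),
            base_means=dict(zip(ab_ids, mu0)),
        ),
    )
    return umat, truth


def simulate_screen(
    n_probes: int = 294,
    n_phenotypes: int = 70,
    n_kinases: int = 225,
    n_true_kinases: int = 13,
    members_per_kinase: int = 14,
    n_active_probes: int = 18,
    axis_strength: float = 12.0,
    axis_scales: tuple[float, ...] = (5.0, 3.5),
    noise_sd: float = 1.0,
    n_axes: int = 2,
    inhibition_high: tuple[float, float] = (70.0, 95.0),
    inhibition_background: tuple[float, float] = (10.0, 4.0),
    seed: int = 0,
) -> tuple[ScreenMatrix, pd.DataFrame, TruthRecord]:
    """Signed-p screen matrix with planted low-rank axes and kinase sets.

    Two planted orthogonal axes emulate the dominant screen structure: a
    "signalling" axis loading on the first half of the phenotypes and a
    "differentiation" axis loading on a marker block of the second half.
    Per-probe axis activities are N(0, scale^2) with ``axis_scales`` sized so
    the leading components carry a realistic share (roughly 40%) of total
    variance over the unit-variance phenotype noise.

    A pool of ``n_active_probes`` differentiation-inducing probes is shifted
    by ``axis_strength`` on the differentiation axis; each of the
    ``n_true_kinases`` planted kinases draws its ``members_per_kinase``
    inhibitory probes from that pool, so true sets overlap — mirroring the
    cross-reactivity of real kinase-inhibitor probes.  The inhibition matrix
    gives planted members high % inhibition (uniform in ``inhibition_high``)
    and an approximately normal background (mean, sd in
    ``inhibition_background``, clipped to [0, 100]) elsewhere, so the
    outlier-assignment false-positive rate matches its nominal level.
    """
    if n_axes < 1 or n_axes > min(n_probes, n_phenotypes):
        raise ValueError("invalid number of planted axes")
    if n_true_kinases > n_kinases:
        raise ValueError("more true kinases than kinases")
    if members_per_kinase > n_active_probes:
        raise ValueError("members_per_kinase cannot exceed the active pool")
    if n_active_probes > n_probes:
        raise ValueError("active pool larger than the screen")
    rng = np.random.default_rng(seed)
    probes = [f"probe{i + 1:03d}" for i in range(n_probes)]
    phenos = [f"phen{i + 1:03d}" for i in range(n_phenotypes)]
    kinases = [f"KIN{i + 1:03d}" for i in range(n_kinases)]

    # orthonormal axis loadings over phenotypes
    half = n_phenotypes // 2
    load = np.zeros((n_axes, n_phenotypes))
    load[0, :half] = 1.0
    if n_axes > 1:
        load[1, half : half + max(half // 2, 1)] = 1.0
    for j in range(2, n_axes):
        load[j] = rng.normal(size=n_phenotypes)
    # Gram-Schmidt for orthonormality
    for j in range(n_axes):
        for k in range(j):
            load[j] -= (load[j] @ load[k]) * load[k]
        load[j] /= np.linalg.norm(load[j])

    # active differentiation-inducing probe pool; true kinase sets draw their
    # members from it with overlap (probe cross-reactivity)
    active_idx = sorted(rng.choice(n_probes, size=n_active_probes, replace=False))
    members: dict[str, list[str]] = {}
    for k in range(n_true_kinases):
        take = rng.choice(active_idx, size=members_per_kinase, replace=False)
        members[kinases[k]] = sorted(probes[i] for i in take)

    # per-probe axis activities; differentiation axis shifted for the pool
    scales = np.ones(n_axes)
    scales[: len(axis_scales)] = axis_scales[:n_axes]
    scores = rng.normal(size=(n_probes, n_axes)) * scales
    diff_axis = min(1, n_axes - 1)
    scores[active_idx, diff_axis] += axis_strength
    signal = scores @ load
    values = signal + rng.normal(scale=noise_sd, size=(n_probes, n_phenotypes))
    matrix = ScreenMatrix(pd.DataFrame(values, index=probes, columns=phenos))

    bg_mean, bg_sd = inhibition_background
    inhib = np.clip(rng.normal(bg_mean, bg_sd, size=(n_probes, n_kinases)), 0, 100)
    for k, kin in enumerate(kinases):
        if kin in members:
            idx = [probes.index(p) for p in members[kin]]
            inhib[idx, k] = rng.uniform(*inhibition_high, size=len(idx))
    inhibition = pd.DataFrame(inhib, index=probes, columns=kinases)

    truth = TruthRecord(
        kind="screen",
        seed=seed,
        params=dict(
            n_probes=n_probes,
            n_phenotypes=n_phenotypes,
            n_kinases=n_kinases,
            n_true_kinases=n_true_kinases,
            members_per_kinase=members_per_kinase,
            n_active_probes=n_active_probes,
            axis_strength=axis_strength,
            axis_scales=list(axis_scales),
            noise_sd=noise_sd,
            n_axes=n_axes,
        ),
        truth=dict(
            axes=load,
            probe_scores=scores,
            members=members,
            active_probes=[probes[i] for i in active_idx],
            true_kinases=kinases[:n_true_kinases],
            differentiation_axis=int(diff_axis),
        ),
    )
    return matrix, inhibition, truth
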