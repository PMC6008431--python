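"""Readers/writers for panel tables, plate maps, count matrices and configs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .readmodel import AntibodyPanel, PlateMap, ReadLayout


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_panel(path) -> AntibodyPanel:
    """Antibody panel from TSV/CSV with columns antibody_id, barcode[, spike_in]."""
    return AntibodyPanel.from_table(_read_table(path))


def read_plate_map(path) -> PlateMap:
    """Plate map from TSV/CSV with columns well_id, barcode[, covariates...]."""
    return PlateMap.from_table(_read_table(path))


def write_panel(panel: AntibodyPanel, path) -> None:
    df = pd.DataFrame(
        {
            "antibody_id": panel.ids,
            "barcode": [panel.entries[a] for a in panel.ids],
            "spike_in": [a in panel.spike_in for a in panel.ids],
        }
    )
    df.to_csv(path, sep="\t" if str(path).endswith(".tsv") else ",", index=False)


def write_plate_map(plate: PlateMap, path) -> None:
    plate.wells.rename_axis("well_id").to_csv(
        path, sep="\t" if str(path).endswith(".tsv") else ","
    )


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    return df


def read_layout(path) -> ReadLayout:
    with open(path) as fh:
        return ReadLayout.from_dict(yaml.safe_load(fh))


def write_layout(layout: ReadLayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout.to_dict(), fh, sort_keys=True)
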