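"""Reading and writing the on-disk formats.

Images travel as multi-page TIFF (one page per channel) with a JSON sidecar
recording pixel size and channel names; masks as 8-bit label TIFFs; ground
truth, section series and plot bundles as JSON; measurement tables as CSV
with columns ``group, hemisphere, variable, value``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    AnnotatedImage,
    ElementalMap,
    GroundTruth,
    PunctumTruth,
    Section,
    SectionSeries,
)

__all__ = [
    "save_annotated_image", "load_annotated_image",
    "save_ground_truth", "load_ground_truth",
    "save_section_series", "load_section_series",
    "save_elemental_map", "load_elemental_map",
    "save_measurement_table", "load_measurement_table",
]

TABLE_COLUMNS = ["group", "hemisphere", "variable", "value"]


def save_annotated_image(image: AnnotatedImage, prefix: str | Path) -> None:
    """Write ``<prefix>.tif`` (channels), mask TIFFs and a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(f"{prefix}.tif", stack)
    tifffile.imwrite(f"{prefix}_soma.tif", image.soma_mask.astype(np.uint8))
    tifffile.imwrite(f"{prefix}_nucleus.tif", image.nucleus_mask.astype(np.uint8))
    sidecar = {"channels": names, "pixel_size_um": image.pixel_size_um,
               "z_plane_id": image.z_plane_id}
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def load_annotated_image(prefix: str | Path) -> AnnotatedImage:
    prefix = Path(prefix)
    sidecar = json.loads(Path(f"{prefix}.json").read_text())
    stack = tifffile.imread(f"{prefix}.tif")
    if stack.ndim == 2:
        stack = stack[None]
    channels = {n: stack[i].astype(float)
                for i, n in enumerate(sidecar["channels"])}
    return AnnotatedImage(
        channels=channels,
        pixel_size_um=float(sidecar["pixel_size_um"]),
        soma_mask=tifffile.imread(f"{prefix}_soma.tif") > 0,
        nucleus_mask=tifffile.imread(f"{prefix}_nucleus.tif") > 0,
        z_plane_id=sidecar.get("z_plane_id", "z0"),
    )


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2))


def load_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    data["puncta_catalog"] = [
        PunctumTruth(centre_um=tuple(p["centre_um"]), radius_um=p["radius_um"],
                     compartment=p["compartment"])
        for p in data.get("puncta_catalog", [])]
    return GroundTruth(**data)


def save_section_series(series: SectionSeries, path: str | Path) -> None:
    data = {
        "thickness_um": series.thickness_um,
        "region_size_um": list(series.region_size_um),
        "section_period": series.section_period,
        "sections": [{"index": s.index, "sampled": s.sampled,
                      "points_um": s.points_um.tolist()}
                     for s in series.sections],
    }
    Path(path).write_text(json.dumps(data))


def load_section_series(path: str | Path) -> SectionSeries:
    data = json.loads(Path(path).read_text())
    sections = [Section(index=s["index"], sampled=s["sampled"],
                        points_um=np.asarray(s["points_um"], dtype=float))
                for s in data["sections"]]
    return SectionSeries(sections=sections,
                         thickness_um=data["thickness_um"],
                         region_size_um=tuple(data["region_size_um"]),
                         section_period=data.get("section_period", 1))


def save_elemental_map(emap: ElementalMap, prefix: str | Path) -> None:
    """Write ``<prefix>.tif`` plus a JSON sidecar with element and step size."""
    prefix = Path(prefix)
    tifffile.imwrite(f"{prefix}.tif", emap.grid.astype(np.float32))
    Path(f"{prefix}.json").write_text(json.dumps(
        {"element": emap.element, "step_um": emap.step_um}))


def load_elemental_map(prefix: str | Path) -> ElementalMap:
    prefix = Path(prefix)
    sidecar = json.loads(Path(f"{prefix}.json").read_text())
    return ElementalMap(element=sidecar["element"],
                        grid=tifffile.imread(f"{prefix}.tif").astype(float),
                        step_um=float(sidecar["step_um"]))


def save_measurement_table(table: pd.DataFrame, path: str | Path) -> None:
    table[TABLE_COLUMNS].to_csv(path, index=False)


def load_measurement_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    return table
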