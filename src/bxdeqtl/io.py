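"""Delimited-text dialects for every on-disk artifact.

All files are tab-separated UTF-8 with optional ``#``-prefixed comment
lines. Four input dialects:

* genotypes: header row of marker ids, three map rows (``chrom``, ``cm``,
  ``mb``), then one row per strain with codes B / D / U (U = missing);
* signals: header row of probe ids, one row per array;
* sample sheet: array_id, strain_id, sex, is_f1;
* probe sheet: probe_id, symbol, chrom, mb (``unmapped`` probes carry NA).

Output tables (scan results, peak catalogs, heritability, correlation
pairs, signature reports) are written with deterministic row/column order
and floats at 6 significant digits, so identical inputs produce
byte-identical files. Readers reject malformed input instead of coercing.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    B_CODE,
    D_CODE,
    ExpressionPanel,
    GenotypeMatrix,
    MarkerMap,
    ParseError,
    ValidationError,
)
from .simulate import SimulationConfig, TruthTable

_CODE_TO_NUM = {"B": B_CODE, "D": D_CODE, "U": np.nan}
_NUM_TO_CODE = {B_CODE: "B", D_CODE: "D"}

FLOAT_FORMAT = "%.6g"


def _read_lines(path) -> list[list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    mm = genotypes.map.table
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(mm["marker_id"]) + "\n")
        fh.write("chrom\t" + "\t".join(mm["chrom"]) + "\n")
        fh.write("cm\t" + "\t".join(FLOAT_FORMAT % v for v in mm["cm"]) + "\n")
        fh.write("mb\t" + "\t".join(FLOAT_FORMAT % v for v in mm["mb"]) + "\n")
        for strain, row in genotypes.calls.iterrows():
            codes = ["U" if np.isnan(v) else _NUM_TO_CODE[v] for v in row.to_numpy()]
            fh.write(strain + "\t" + "\t".join(codes) + "\n")


def read_genotypes(path) -> GenotypeMatrix:
    """Parse the genotype dialect; unknown codes raise a located ParseError."""
    rows = _read_lines(path)
    if len(rows) < 5:
        raise ParseError(f"genotype file {path} too short (need map rows and >=1 strain)")
    header, chrom_row, cm_row, mb_row = rows[0], rows[1], rows[2], rows[3]
    if chrom_row[0] != "chrom" or cm_row[0] != "cm" or mb_row[0] != "mb":
        raise ParseError("genotype file must have chrom/cm/mb rows after the header")
    marker_ids = header[1:]
    mm = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": marker_ids,
                "chrom": chrom_row[1:],
                "cm": [float(v) for v in cm_row[1:]],
                "mb": [float(v) for v in mb_row[1:]],
            }
        )
    )
    strains, data = [], []
    for row in rows[4:]:
        strain = row[0]
        codes = row[1:]
        if len(codes) != len(marker_ids):
            raise ParseError(f"strain row {strain!r} has {len(codes)} codes, expected {len(marker_ids)}")
        vals = []
        for j, c in enumerate(codes):
            if c not in _CODE_TO_NUM:
                raise ParseError(
                    f"unknown genotype code {c!r} at strain {strain!r}, marker {marker_ids[j]!r}"
                )
            vals.append(_CODE_TO_NUM[c])
        strains.append(strain)
        data.append(vals)
    calls = pd.DataFrame(data, index=strains, columns=marker_ids)[mm.marker_ids]
    return GenotypeMatrix(calls, mm)


def write_expression(panel: ExpressionPanel, path_signals, path_samples, path_probes) -> None:
    sig = panel.signals.copy()
    sig.insert(0, "array_id", sig.index)
    sig.to_csv(path_signals, sep="\t", index=False, float_format="%.8g")

    samp = panel.samples.reset_index()
    samp.columns = ["array_id", "strain_id", "sex", "is_f1"]
    samp["is_f1"] = samp["is_f1"].astype(bool).map({True: "1", False: "0"})
    samp.to_csv(path_samples, sep="\t", index=False)

    pr = panel.probes.reset_index()
    pr.columns = ["probe_id", "symbol", "chrom", "mb"]
    pr.to_csv(path_probes, sep="\t", index=False, float_format="%.8g", na_rep="NA")


def read_expression(path_signals, path_samples, path_probes) -> ExpressionPanel:
    """Read and cross-validate the three expression files.

    Every array in the signal matrix must have sample metadata; every probe
    must be annotated (possibly as unmapped); negative signals are rejected.
    """
    for p in (path_signals, path_samples, path_probes):
        if not Path(p).exists():
            raise FileNotFoundError(f"no such file: {p}")
    signals = pd.read_csv(path_signals, sep="\t", comment="#").set_index("array_id")
    signals.index = signals.index.astype(str)

    samples = pd.read_csv(path_samples, sep="\t", comment="#", dtype={"array_id": str})
    required = {"array_id", "strain_id", "sex", "is_f1"}
    if not required.issubset(samples.columns):
        raise ParseError(f"sample sheet missing columns: {sorted(required - set(samples.columns))}")
    samples = samples.set_index("array_id")
    samples["is_f1"] = samples["is_f1"].astype(int).astype(bool)

    probes = pd.read_csv(
        path_probes, sep="\t", comment="#", dtype={"probe_id": str}, na_values=["NA"]
    )
    required = {"probe_id", "symbol", "chrom", "mb"}
    if not required.issubset(probes.columns):
        raise ParseError(f"probe sheet missing columns: {sorted(required - set(probes.columns))}")
    probes = probes.set_index("probe_id")

    orphan = [a for a in signals.index if a not in samples.index]
    if orphan:
        raise ValidationError(f"arrays without sample metadata: {orphan}")
    return ExpressionPanel(samples, probes, signals)


def write_table(df: pd.DataFrame, path, comments: tuple[str, ...] = ()) -> None:
    """Write an output table: TSV, 6 significant digits, optional comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_truth(truth: TruthTable, path) -> None:
    payload = {
        "cis_effects": [list(t) for t in truth.cis_effects],
        "trans_effects": [list(t) for t in truth.trans_effects],
        "module_members": truth.module_members,
        "module_driver": None
        if truth.module_driver is None
        else {
            "index": truth.module_driver.index.tolist(),
            "columns": truth.module_driver.columns.tolist(),
            "values": truth.module_driver.to_numpy().tolist(),
        },
        "sex_probes": truth.sex_probes,
        "mendelian_probes": truth.mendelian_probes,
        "h2_targets": truth.h2_targets,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> TruthTable:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    driver = None
    if payload.get("module_driver") is not None:
        d = payload["module_driver"]
        driver = pd.DataFrame(d["values"], index=d["index"], columns=d["columns"])
    return TruthTable(
        cis_effects=[tuple(t) for t in payload["cis_effects"]],
        trans_effects=[tuple(t) for t in payload["trans_effects"]],
        module_members=payload["module_members"],
        module_driver=driver,
        sex_probes=payload["sex_probes"],
        mendelian_probes=payload["mendelian_probes"],
        h2_targets=payload["h2_targets"],
    )


def write_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ParseError(f"config file {path} is not a key:value mapping")
    return out
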