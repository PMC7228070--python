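"""File formats: helical-parameter tables, FASTA duplexes, parameter configs.

Two tabular dialects are supported for trajectories, both plain text with
angles in degrees and rise in Angstrom:

* ``long`` — one row per frame x step with header columns
  ``frame step twist roll tilt [rise]``, tab-separated;
* ``series`` — the per-parameter matrix convention of helical-analysis
  tools: one whitespace-delimited block per parameter (``<base>.twist.ser``
  etc.), rows = frames with a leading frame index, columns = steps.

Round trips are lossless to well below 1e-9 and the two layouts
interconvert exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .elastic import HelicalTrajectory
from .ising import IsingParameters
from .sequences import CANONICAL_STEPS, DuplexSequence

_SERIES_PARAMS = ("twist", "roll", "tilt", "rise")
_FLOAT_FMT = "%.12g"


def write_helical_table(
    traj: HelicalTrajectory, path: str | Path, dialect: str = "long"
) -> None:
    """Write a trajectory in the requested dialect.

    For ``series`` the path is a base name; one ``<base>.<param>.ser``
    file is written per available parameter.
    """
    path = Path(path)
    if dialect == "long":
        traj.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif dialect == "series":
        for param in _SERIES_PARAMS:
            values = getattr(traj, param)
            if values is None:
                continue
            out = np.column_stack([np.arange(1, traj.n_frames + 1), values])
            np.savetxt(path.parent / f"{path.name}.{param}.ser", out, fmt=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'series'")


def read_helical_table(path: str | Path, dialect: str = "long") -> HelicalTrajectory:
    """Read a trajectory table, validating shape and completeness."""
    path = Path(path)
    if dialect == "long":
        return _read_long(path)
    if dialect == "series":
        return _read_series(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'series'")


def _read_long(path: Path) -> HelicalTrajectory:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    required = {"frame", "step", "twist", "roll", "tilt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[df[list(required)].isna().any(axis=1)]
    if not bad.empty:
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in bad.index[:5]]
        raise ValueError(f"{path}: missing values at line(s) {lines}")
    frames = np.sort(df["frame"].unique())
    steps = np.sort(df["step"].unique())
    if len(df) != len(frames) * len(steps):
        raise ValueError(
            f"{path}: ragged table ({len(df)} rows for "
            f"{len(frames)} frames x {len(steps)} steps)"
        )
    df = df.sort_values(["frame", "step"])
    shape = (len(frames), len(steps))
    kwargs = {
        p: df[p].to_numpy().reshape(shape) for p in ("twist", "roll", "tilt")
    }
    if "rise" in df.columns and not df["rise"].isna().any():
        kwargs["rise"] = df["rise"].to_numpy().reshape(shape)
    return HelicalTrajectory(step_labels=[int(s) for s in steps], **kwargs)


def _read_series(base: Path) -> HelicalTrajectory:
    kwargs = {}
    for param in _SERIES_PARAMS:
        f = base.parent / f"{base.name}.{param}.ser"
        if not f.exists():
            if param == "rise":
                continue
            raise FileNotFoundError(f"series dialect needs {f}")
        try:
            block = np.loadtxt(f, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{f}: malformed series block: {exc}") from exc
        kwargs[param] = block[:, 1:]  # drop the leading frame index
    shapes = {k: v.shape for k, v in kwargs.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"{base}: inconsistent series shapes {shapes}")
    return HelicalTrajectory(**kwargs)


def read_duplex_fasta(
    path: str | Path,
    active_region: tuple[int, int] | None = None,
    melt_region: tuple[int, int] | None = None,
) -> DuplexSequence:
    """Load a duplex from a single-record FASTA of the top strand."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    bases = str(rec.seq).lower()
    bad = set(bases) - set("acgt")
    if bad:
        raise ValueError(
            f"{path}: ambiguity codes or invalid characters {sorted(bad)}"
        )
    kwargs = {}
    if active_region is not None:
        kwargs["active_start"], kwargs["active_end"] = active_region
    return DuplexSequence(
        bases, melt_region=melt_region, label=rec.id or "", **kwargs
    )


def params_to_dict(params: IsingParameters) -> dict:
    return {
        "stacking": dict(params.stacking),
        "pairing": dict(params.pairing),
        "epsilon": params.epsilon,
        "c_bubble": params.c_bubble,
        "tau0": params.tau0,
        "p_twist": params.p_twist,
        "contour_l": params.contour_l,
        "temperature": params.temperature,
        "pairing_double_count": params.pairing_double_count,
    }


def write_params(params: IsingParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def read_params(path: str | Path) -> IsingParameters:
    """Load melting-model parameters from YAML (or JSON, a YAML subset).

    The file is validated against the parameter schema: every one of the
    ten canonical dinucleotide steps must carry a stacking energy, both
    pairing classes must be present, and all constants must be positive.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter fields")
    known = set(params_to_dict(IsingParameters()))
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter fields {sorted(unknown)}")
    if "stacking" in raw:
        missing = [s for s in CANONICAL_STEPS if s not in raw["stacking"]]
        if missing:
            raise ValueError(f"{path}: stacking table missing steps {missing}")
    if "pairing" in raw:
        missing = [c for c in ("at", "gc") if c not in raw["pairing"]]
        if missing:
            raise ValueError(f"{path}: pairing table missing classes {missing}")
    try:
        return IsingParameters(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid parameters: {exc}") from exc


def default_params_path() -> Path:
    """Path of the packaged default parameter file."""
    return Path(__file__).parent / "data" / "ising_defaults.yaml"


def write_melting_profile_tsv(
    path: str | Path, sigma, delta_tau, free_energy, p_any_melt
) -> None:
    """Profile TSV: sigma, delta_tau_deg, free_energy_kcal_mol, p_any_melt."""
    pd.DataFrame(
        {
            "sigma": sigma,
            "delta_tau_deg": delta_tau,
            "free_energy_kcal_mol": free_energy,
            "p_any_melt": p_any_melt,
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_pmelt_tsv(path: str | Path, p_melt: np.ndarray) -> None:
    """Per-base melting probabilities, 1-based inclusive positions."""
    pd.DataFrame(
        {"base_pair": np.arange(1, len(p_melt)), "p_melt": p_melt[1:]}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_pmelt_bedgraph(
    path: str | Path, p_melt: np.ndarray, chrom: str = "duplex"
) -> None:
    """bedGraph export: 0-based half-open, i.e. bp i -> [i-1, i)."""
    with open(path, "w") as fh:
        for i, p in enumerate(p_melt[1:], start=1):
            fh.write(f"{chrom}\t{i - 1}\t{i}\t{_FLOAT_FMT % p}\n")
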