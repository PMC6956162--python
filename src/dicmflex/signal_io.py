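"""Recording containers, lobar sensor layouts, and the subnetwork table.

The native on-disk container is a small HDF5 schema (datasets ``/data``,
``/fs``, ``/channel_names``, root attribute ``system``); a delimited-text
(TSV + JSON sidecar) form is supported for toy fixtures and FIF reading is
delegated to MNE when available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .codes import Estimator, cross_code, within_code

LOBES = ("frontal", "temporal", "parietal", "parieto-occipital", "occipital")
HEMISPHERES = ("L", "R")


class RecordingFormatError(ValueError):
    """The file does not conform to a supported recording schema."""


class RecordingValidationError(ValueError):
    """The recording content violates an invariant (NaN/Inf, bad fs, ...)."""


@dataclass
class Recording:
    """A multichannel recording: channels x samples with a sampling rate."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    system: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise RecordingValidationError(
                f"data must be 2-D (channels x samples), got {self.data.ndim}-D"
            )
        if not np.isfinite(self.data).all():
            raise RecordingValidationError("recording contains NaN or Inf samples")
        if not (np.isscalar(self.fs) or np.ndim(self.fs) == 0) or not self.fs > 0:
            raise RecordingValidationError(f"sampling rate must be > 0, got {self.fs}")
        self.fs = float(self.fs)
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[0]:
            raise RecordingValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to the native HDF5 container (or TSV for ``.tsv``)."""
    path = Path(path)
    if path.suffix == ".tsv":
        frame = pd.DataFrame(rec.data.T, columns=rec.channel_names)
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
        sidecar = {"fs": rec.fs, "system": rec.system}
        path.with_suffix(".json").write_text(json.dumps(sidecar))
        return path
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=rec.fs)
        f.create_dataset(
            "channel_names",
            data=np.array([c.encode() for c in rec.channel_names]),
        )
        f.attrs["system"] = rec.system
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from HDF5, TSV (+JSON sidecar), or FIF.

    The format is inferred from the suffix when not given.  FIF reading is
    delegated to MNE; channels are exported in native sensor units.
    """
    path = Path(path)
    if format is None:
        format = {".h5": "hdf5", ".hdf5": "hdf5", ".tsv": "tsv", ".fif": "fif"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise RecordingFormatError(f"cannot infer format from suffix: {path.name}")
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "fs" not in f:
                raise RecordingFormatError(f"{path.name}: missing /fs dataset")
            if "data" not in f or "channel_names" not in f:
                raise RecordingFormatError(f"{path.name}: missing /data or /channel_names")
            return Recording(
                data=f["data"][()],
                fs=float(f["fs"][()]),
                channel_names=[c.decode() for c in f["channel_names"][()]],
                system=str(f.attrs.get("system", "unknown")),
            )
    if format == "tsv":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise RecordingFormatError(f"{path.name}: missing JSON sidecar with fs")
        sidecar = json.loads(sidecar_path.read_text())
        if "fs" not in sidecar:
            raise RecordingFormatError(f"{sidecar_path.name}: sidecar lacks 'fs'")
        frame = pd.read_csv(path, sep="\t")
        return Recording(
            data=frame.to_numpy().T,
            fs=float(sidecar["fs"]),
            channel_names=list(frame.columns),
            system=str(sidecar.get("system", "unknown")),
        )
    if format == "fif":
        import mne

        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        return Recording(
            data=raw.get_data(),
            fs=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
            system="fif",
        )
    raise RecordingFormatError(f"unsupported format: {format}")


# ---------------------------------------------------------------------------
# Lobar layouts
# ---------------------------------------------------------------------------

@dataclass
class LobarLayout:
    """Assignment of every channel to one (lobe, hemisphere) group."""

    lobe_of: dict[str, tuple[str, str]]
    system: str = "custom"

    def __post_init__(self) -> None:
        present: dict[str, set[str]] = {}
        for ch, (lobe, hemi) in self.lobe_of.items():
            if lobe not in LOBES:
                raise ValueError(f"channel {ch}: unknown lobe {lobe!r}")
            if hemi not in HEMISPHERES:
                raise ValueError(f"channel {ch}: hemisphere must be L or R, got {hemi!r}")
            present.setdefault(lobe, set()).add(hemi)
        for lobe, hemis in present.items():
            if hemis != {"L", "R"}:
                raise ValueError(
                    f"lobe {lobe!r} present in only one hemisphere ({sorted(hemis)})"
                )

    def groups(self) -> dict[tuple[str, str], list[str]]:
        out: dict[tuple[str, str], list[str]] = {}
        for ch, key in self.lobe_of.items():
            out.setdefault(key, []).append(ch)
        return out

    def channels(self, lobe: str, hemi: str) -> list[str]:
        return [ch for ch, key in self.lobe_of.items() if key == (lobe, hemi)]

    def n_sensors(self, lobe: str, hemi: str) -> int:
        return len(self.channels(lobe, hemi))

    def indices(self, channel_names: list[str], lobe: str, hemi: str) -> np.ndarray:
        """Row indices (into a recording's channel list) of one lobar group."""
        members = set(self.channels(lobe, hemi))
        return np.array(
            [i for i, ch in enumerate(channel_names) if ch in members], dtype=int
        )


def load_layout(
    spec: str | Path | dict, channel_names: list[str] | None = None
) -> LobarLayout:
    """Build a :class:`LobarLayout` from a YAML file or an in-memory mapping.

    The mapping is ``channel -> "lobe/H"`` or ``channel -> [lobe, H]``.  When
    ``channel_names`` is given every one of them must be covered.
    """
    system = "custom"
    if isinstance(spec, (str, Path)):
        loaded = yaml.safe_load(Path(spec).read_text())
        system = str(loaded.get("system", "custom"))
        mapping = loaded["channels"]
    else:
        mapping = spec
    lobe_of: dict[str, tuple[str, str]] = {}
    for ch, value in mapping.items():
        if isinstance(value, str):
            lobe, hemi = value.rsplit("/", 1)
        else:
            lobe, hemi = value
        lobe_of[str(ch)] = (lobe, hemi)
    if channel_names is not None:
        missing = [ch for ch in channel_names if ch not in lobe_of]
        if missing:
            raise ValueError(f"layout does not map channels: {', '.join(missing)}")
        lobe_of = {ch: lobe_of[ch] for ch in channel_names}
    return LobarLayout(lobe_of=lobe_of, system=system)


def packaged_layout(system: str) -> LobarLayout:
    """Load a packaged approximate sensor-to-lobe map.

    ``system`` is ``"magnes248"`` or ``"ctf275"``.  The maps partition the
    sensor array into the ten lobe-hemisphere groups with plausible lobar
    proportions; they are editable YAML and intentionally approximate — no
    published per-sensor assignment exists for either system.
    """
    ref = resources.files("dicmflex").joinpath(f"layouts/{system}.yaml")
    with resources.as_file(ref) as p:
        return load_layout(p)


# ---------------------------------------------------------------------------
# Subnetwork configuration (the ranked feature table)
# ---------------------------------------------------------------------------

#: Pair scopes: "cross" = inter-hemispheric pairs only, "within" =
#: intra-hemispheric pairs only (both hemispheres), "both" = all pairs
#: between the two lobes regardless of hemisphere.
SCOPES = ("cross", "within", "both")


@dataclass(frozen=True)
class SubnetworkRow:
    name: str
    lobe_a: str
    lobe_b: str
    scope: str           # one of SCOPES
    hemi_a: str | None   # restrict lobe_a to one hemisphere (L/R) or None
    estimator: int       # estimator id 1-5
    code: int            # frequency code 1-36
    has_fo: bool


@dataclass
class SubnetworkSpec:
    rows: list[SubnetworkRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rows) != 12:
            raise ValueError(f"subnetwork table must have 12 rows, got {len(self.rows)}")
        n_fo = sum(r.has_fo for r in self.rows)
        if n_fo != 10:
            raise ValueError(f"subnetwork table must flag 10 FO rows, got {n_fo}")

    @property
    def n_mss(self) -> int:
        return len(self.rows)

    @property
    def n_fo(self) -> int:
        return sum(r.has_fo for r in self.rows)


def load_table1_spec() -> SubnetworkSpec:
    """The packaged 12-row subnetwork configuration (12 MSS + 10 FO features).

    Band labels that are finer than the 8-band decomposition (gamma
    sub-bands; bare "beta") are mapped to gamma and beta2 respectively; the
    mapping is a fixed package convention.
    """
    E = Estimator
    rows = [
        SubnetworkRow("frontal_cross_delta_aec", "frontal", "frontal", "cross",
                      None, E.AEC, within_code("delta"), True),
        SubnetworkRow("frontal_temporal_theta_gamma_pac", "frontal", "temporal",
                      "both", None, E.PAC, cross_code("theta", "gamma"), True),
        SubnetworkRow("frontal_parietal_theta_alpha2_dste", "frontal", "parietal",
                      "both", None, E.DSTE, cross_code("theta", "alpha2"), True),
        SubnetworkRow("parieto-occipital_cross_alpha1_iplv", "parieto-occipital",
                      "parieto-occipital", "cross", None, E.IPLV,
                      within_code("alpha1"), True),
        SubnetworkRow("frontal_within_theta_iplv", "frontal", "frontal", "within",
                      None, E.IPLV, within_code("theta"), True),
        SubnetworkRow("L_temporal_frontal_delta_beta2_pac", "temporal", "frontal",
                      "cross", "L", E.PAC, cross_code("delta", "beta2"), True),
        SubnetworkRow("R_temporal_frontal_delta_gamma_pac", "temporal", "frontal",
                      "both", "R", E.PAC, cross_code("delta", "gamma"), False),
        SubnetworkRow("L_parietal_parieto-occipital_alpha1_iplv", "parietal",
                      "parieto-occipital", "both", "L", E.IPLV,
                      within_code("alpha1"), True),
        SubnetworkRow("parieto-occipital_cross_beta2_aec", "parieto-occipital",
                      "parieto-occipital", "cross", None, E.AEC,
                      within_code("beta2"), True),
        SubnetworkRow("R_temporal_parieto-occipital_gamma_iplv", "temporal",
                      "parieto-occipital", "both", "R", E.IPLV,
                      within_code("gamma"), True),
        SubnetworkRow("temporal_cross_beta2_aec", "temporal", "temporal", "cross",
                      None, E.AEC, within_code("beta2"), True),
        SubnetworkRow("occipital_cross_alpha2_gamma_pac", "occipital", "occipital",
                      "cross", None, E.PAC, cross_code("alpha2", "gamma"), False),
    ]
    return SubnetworkSpec(rows=[
        SubnetworkRow(r.name, r.lobe_a, r.lobe_b, r.scope, r.hemi_a,
                      int(r.estimator), r.code, r.has_fo)
        for r in rows
    ])
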