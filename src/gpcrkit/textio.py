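"""Plain-text serialization for spectra, FIDs, kinetic traces and surfaces.

All formats are delimited text with ``#``-commented headers naming units, so
artifacts stay diffable and portable.
"""

from __future__ import annotations

import numpy as np

from .kinetics import KineticTrace
from .nmr import FID, SpectrumModel
from .reweight import FESGrid

__all__ = ["save_spectrum", "load_spectrum", "save_fid", "load_fid",
           "save_trace", "load_trace", "save_fes", "load_fes",
           "save_trajectory", "load_trajectory"]


def save_trajectory(frag, path) -> None:
    """Columnar text for a trajectory fragment: time, per-term V, per-term
    boost, then coordinates."""
    ndim = frag.coords.shape[1]
    header = ("time_ps v_soft_kcal v_total_kcal dv_soft_kcal dv_total_kcal "
              + " ".join(f"x{i}" for i in range(ndim)))
    data = np.column_stack([frag.times, frag.v_soft, frag.v_total,
                            frag.dv_soft, frag.dv_total, frag.coords])
    np.savetxt(path, data, header=header, comments="# ")


def load_trajectory(path):
    from .gamd import TrajectoryFragment

    data = np.atleast_2d(np.loadtxt(path))
    return TrajectoryFragment(times=data[:, 0], coords=data[:, 5:],
                              v_soft=data[:, 1], v_total=data[:, 2],
                              dv_soft=data[:, 3], dv_total=data[:, 4])


def save_spectrum(spectrum: SpectrumModel, path) -> None:
    np.savetxt(path, np.column_stack([spectrum.axis_hz, spectrum.intensities]),
               header="frequency_Hz intensity_au", comments="# ")


def load_spectrum(path) -> SpectrumModel:
    data = np.loadtxt(path)
    return SpectrumModel(data[:, 0], data[:, 1], provenance={"path": str(path)})


def save_fid(fid: FID, path) -> None:
    np.savetxt(path, np.column_stack([fid.times, fid.samples.real, fid.samples.imag]),
               header=f"time_s real imag (dwell_s={fid.dwell!r})", comments="# ")


def load_fid(path) -> FID:
    data = np.loadtxt(path)
    dwell = data[1, 0] - data[0, 0]
    return FID(data[:, 1] + 1j * data[:, 2], dwell)


def save_trace(trace: KineticTrace, path) -> None:
    np.savetxt(path, np.column_stack([trace.times, trace.signal]),
               header=f"time_s signal_M (noise_sd={trace.noise_sd!r})", comments="# ")


def load_trace(path) -> KineticTrace:
    data = np.loadtxt(path)
    return KineticTrace(data[:, 0], data[:, 1])


def save_fes(fes: FESGrid, path) -> None:
    """Edges in the header; one row per bin: indices, count, dV stats, F, mask."""
    with open(path, "w") as fh:
        fh.write(f"# dimension {fes.dimension} temperature_K {fes.temperature} "
                 f"cutoff {fes.cutoff}\n")
        for ax, e in enumerate(fes.edges):
            fh.write(f"# edges{ax} " + " ".join(f"{v:.10g}" for v in e) + "\n")
        fh.write("# bin_indices count dv_mean dv_sd free_energy_kcal_mol masked\n")
        it = np.ndindex(fes.counts.shape)
        for idx in it:
            fh.write(" ".join(str(i) for i in idx)
                     + f" {fes.counts[idx]:.0f} {fes.dv_mean[idx]:.8g}"
                     f" {fes.dv_sd[idx]:.8g} {fes.free_energy[idx]:.8g}"
                     f" {int(fes.mask[idx])}\n")


def load_fes(path) -> FESGrid:
    edges = []
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "dimension":
                    meta = {parts[0]: int(parts[1]), parts[2]: float(parts[3]),
                            parts[4]: int(parts[5])}
                elif parts and parts[0].startswith("edges"):
                    edges.append(np.array([float(v) for v in parts[1:]]))
                continue
            rows.append([float(v) for v in line.split()])
    dim = meta["dimension"]
    shape = tuple(e.size - 1 for e in edges)
    counts = np.zeros(shape)
    dv_mean = np.zeros(shape)
    dv_sd = np.zeros(shape)
    f = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for r in rows:
        idx = tuple(int(v) for v in r[:dim])
        counts[idx], dv_mean[idx], dv_sd[idx], f[idx] = r[dim:dim + 4]
        mask[idx] = bool(int(r[dim + 4]))
    return FESGrid(edges, counts, dv_mean, dv_sd, f, mask,
                   meta["temperature_K"], meta["cutoff"])
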