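"""HDF5 / TIFF / CSV serialization of the pipeline's artifacts."""

from __future__ import annotations

import numpy as np

from .doppler import PowerDopplerImage, to_db
from .forward import SpatiotemporalBlock
from .ulm import LocalizationSet, UlmImage
from .vasculature import ScattererTrajectorySet, VesselTree

__all__ = [
    "save_block", "load_block", "save_tree", "load_tree",
    "save_trajectories", "load_trajectories", "save_ulm", "load_ulm",
    "save_power_doppler", "save_localizations", "load_localizations",
    "vessel_mask", "save_image_tiff",
]


def save_block(group, block: SpatiotemporalBlock, name: str = "block") -> None:
    """Write a block into an open h5py group/file."""
    ds = group.create_dataset(name, data=block.data, chunks=True)
    ds.attrs["pixel_pitch"] = block.pixel_pitch
    ds.attrs["frame_rate"] = block.frame_rate
    ds.attrs["kind"] = block.kind


def load_block(group, name: str = "block") -> SpatiotemporalBlock:
    ds = group[name]
    return SpatiotemporalBlock(data=ds[...], pixel_pitch=float(ds.attrs["pixel_pitch"]),
                               frame_rate=float(ds.attrs["frame_rate"]),
                               kind=str(ds.attrs["kind"]))


def save_tree(group, tree: VesselTree) -> None:
    group.attrs["field_of_view"] = tree.field_of_view
    group.attrs["n_segments"] = tree.n_segments
    if tree.n_segments:
        group.create_dataset("radii", data=tree.radii)
        group.create_dataset("mean_speeds", data=tree.mean_speeds)
        group.create_dataset("flow_directions", data=tree.flow_directions)
        group.create_dataset("parents", data=np.asarray(tree.parents))
        for i, pts in enumerate(tree.segments):
            group.create_dataset(f"segment_{i:04d}", data=pts)
    if tree.parallel_pair is not None:
        group.attrs["pair_segments"] = tree.parallel_pair["segments"]
        group.attrs["pair_spacing_mm"] = tree.parallel_pair["spacing_mm"]
        group.attrs["pair_cross_line"] = np.asarray(
            tree.parallel_pair["cross_line"]).ravel()


def load_tree(group) -> VesselTree:
    n = int(group.attrs["n_segments"])
    tree = VesselTree(field_of_view=tuple(group.attrs["field_of_view"]))
    if n:
        tree.segments = [group[f"segment_{i:04d}"][...] for i in range(n)]
        tree.radii = group["radii"][...]
        tree.mean_speeds = group["mean_speeds"][...]
        tree.flow_directions = group["flow_directions"][...]
        tree.parents = list(group["parents"][...])
    if "pair_segments" in group.attrs:
        cl = group.attrs["pair_cross_line"].reshape(2, 2)
        tree.parallel_pair = {
            "segments": tuple(int(i) for i in group.attrs["pair_segments"]),
            "spacing_mm": float(group.attrs["pair_spacing_mm"]),
            "cross_line": (tuple(cl[0]), tuple(cl[1]))}
    return tree


def save_trajectories(group, traj: ScattererTrajectorySet) -> None:
    group.create_dataset("positions", data=traj.positions)
    group.create_dataset("amplitudes", data=traj.amplitudes)
    group.create_dataset("alive_mask", data=traj.alive_mask)
    group.create_dataset("segment_index", data=traj.segment_index)
    group.attrs["frame_interval"] = traj.frame_interval


def load_trajectories(group) -> ScattererTrajectorySet:
    return ScattererTrajectorySet(
        positions=group["positions"][...],
        amplitudes=group["amplitudes"][...],
        alive_mask=group["alive_mask"][...].astype(bool),
        frame_interval=float(group.attrs["frame_interval"]),
        segment_index=group["segment_index"][...])


def save_ulm(path_or_group, ulm: UlmImage, as_tiff: bool = False) -> None:
    if as_tiff:
        import tifffile
        tifffile.imwrite(path_or_group, ulm.counts.astype(np.float32))
        return
    g = path_or_group
    g.create_dataset("counts", data=ulm.counts)
    g.attrs["upsampling"] = ulm.upsampling
    g.attrs["pixel_pitch"] = ulm.pixel_pitch


def load_ulm(group) -> UlmImage:
    return UlmImage(counts=group["counts"][...],
                    upsampling=int(group.attrs["upsampling"]),
                    pixel_pitch=float(group.attrs["pixel_pitch"]))


def save_power_doppler(path, pd_img: PowerDopplerImage, *,
                       preview_png=None, dynamic_range_db: float = 70.0) -> None:
    """32-bit linear TIFF plus an optional dB-compressed 8-bit PNG preview."""
    import tifffile
    tifffile.imwrite(path, pd_img.intensity.astype(np.float32))
    if preview_png is not None:
        import imageio.v3 as iio
        img = to_db(pd_img.intensity, dynamic_range_db)
        iio.imwrite(preview_png, (255 * img).astype(np.uint8))


def save_image_tiff(path, image: np.ndarray) -> None:
    import tifffile
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def save_localizations(path, locs: LocalizationSet) -> None:
    np.savetxt(path, locs.events, delimiter=",", fmt="%.6f",
               header="frame,x_mm,z_mm,amplitude", comments="")


def load_localizations(path) -> LocalizationSet:
    ev = np.loadtxt(path, delimiter=",", skiprows=1).reshape(-1, 4)
    return LocalizationSet(events=ev)


def vessel_mask(tree: VesselTree, grid, pixel_pitch: float,
                upsampling: int = 1) -> np.ndarray:
    """Binary lumen mask on the (optionally upsampled) grid: pixels within one
    radius of a vessel centerline.  An auxiliary geometric truth; exportable
    as 16-bit TIFF."""
    Z, X = grid
    R = int(upsampling)
    pitch = pixel_pitch / R
    mask = np.zeros((R * Z, R * X), dtype=bool)
    for i, pts in enumerate(tree.segments):
        # densely resample the polyline, then mark a disc around each point
        d = np.hypot(*np.diff(pts, axis=0).T)
        n = max(int(np.sum(d) / (0.5 * pitch)), 2)
        s = np.linspace(0, np.sum(d), n)
        cum = np.concatenate([[0], np.cumsum(d)])
        px = np.interp(s, cum, pts[:, 0])
        pz = np.interp(s, cum, pts[:, 1])
        r_px = max(int(np.ceil(tree.radii[i] / pitch)), 1)
        iz = np.clip(np.round(pz / pitch).astype(int), 0, R * Z - 1)
        ix = np.clip(np.round(px / pitch).astype(int), 0, R * X - 1)
        for dz in range(-r_px, r_px + 1):
            for dx in range(-r_px, r_px + 1):
                if dz * dz + dx * dx > r_px * r_px:
                    continue
                mask[np.clip(iz + dz, 0, R * Z - 1),
                     np.clip(ix + dx, 0, R * X - 1)] = True
    return mask
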