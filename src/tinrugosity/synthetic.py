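"""Seeded synthetic bathymetry with known analytic structure.

Generators for test terrains standing in for field surveys: flat and
inclined planes, sinusoidal ridges, a peak-and-trough exponential
surface, and correlated random noise fields.  All generators mesh a
regular grid (two triangles per cell via 2.5D Delaunay), the structured
setting of stereo reconstructions; a jittered-grid option produces
irregular TINs.  The analytic height function is attached to the mesh
metadata so tests can check results against closed forms.

The peak-and-trough family is ``z(E, N) = a * N' * exp(-(E'^2 + N'^2))``
with ``E' = E/w, N' = N/w``: one peak, one trough, and a point of
inflection with maximum slope between them.  Defaults a = 1 m, w = 1 m
over a 6 m x 6 m extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TerrainSpecError
from .mesh import TriangleMesh, delaunay_triangulate

__all__ = [
    "TerrainSpec",
    "generate",
    "add_vertex_noise",
    "flat",
    "inclined",
    "sinusoid",
    "peak_trough",
    "noise_field",
]

_FAMILIES = {"flat", "inclined", "sinusoid", "peak_trough", "noise_field"}


@dataclass
class TerrainSpec:
    """Specification of a synthetic terrain patch.

    Parameters
    ----------
    family : str
        One of flat, inclined, sinusoid, peak_trough, noise_field.
    extent : (float, float)
        Easting and Northing spans in metres, centred on the origin.
    resolution : float
        Grid spacing in metres; must be <= min(extent)/4 so the patch is
        meaningfully sampled.
    params : dict
        Family parameters (all lengths in metres, angles in degrees):
        ``depth`` vertical offset (all families, default 0);
        ``slope_deg``/``facing_deg`` for inclined;
        ``amplitude``/``wavelength``/``direction_deg`` for sinusoid;
        ``amplitude``/``width`` for peak_trough;
        ``sigma``/``correlation_length`` for noise_field.
    seed : int
        Seed for stochastic families and grid jitter.
    jitter : float
        Fraction of the grid spacing by which to randomly perturb vertex
        E-N positions (0 = regular grid), for irregular-TIN testing.
    """

    family: str
    extent: tuple = (6.0, 6.0)
    resolution: float = 0.05
    params: dict = field(default_factory=dict)
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise TerrainSpecError(f"unknown terrain family {self.family!r}")
        if np.isscalar(self.extent):
            self.extent = (float(self.extent), float(self.extent))
        self.extent = (float(self.extent[0]), float(self.extent[1]))
        if min(self.extent) <= 0:
            raise TerrainSpecError("extent spans must be positive")
        if not (0 < self.resolution <= min(self.extent) / 4):
            raise TerrainSpecError(
                f"resolution must be in (0, {min(self.extent) / 4:g}] for extent {self.extent}"
            )
        amp = self.params.get("amplitude", 0.0)
        if amp < 0:
            raise TerrainSpecError("amplitude must be >= 0")
        if not (0 <= self.jitter < 0.5):
            raise TerrainSpecError("jitter must be in [0, 0.5)")


def _grid(spec: TerrainSpec) -> tuple[np.ndarray, np.ndarray]:
    half_e, half_n = spec.extent[0] / 2.0, spec.extent[1] / 2.0
    es = np.arange(-half_e, half_e + spec.resolution / 2, spec.resolution)
    ns = np.arange(-half_n, half_n + spec.resolution / 2, spec.resolution)
    ee, nn = np.meshgrid(es, ns, indexing="ij")
    return ee.ravel(), nn.ravel()


def _height_function(spec: TerrainSpec):
    """Closed-form z(E, N) for the deterministic families."""
    p = spec.params
    depth = p.get("depth", 0.0)
    if spec.family == "flat":
        return lambda e, n: np.full_like(np.asarray(e, dtype=float), depth)
    if spec.family == "inclined":
        slope_deg = p.get("slope_deg", 30.0)
        facing = np.radians(p.get("facing_deg", 0.0))
        grad = np.tan(np.radians(slope_deg))
        # normal ~ (tan(a) sin(psi), tan(a) cos(psi), 1): faces `facing_deg`
        return lambda e, n: depth - grad * (
            np.asarray(e) * np.sin(facing) + np.asarray(n) * np.cos(facing)
        )
    if spec.family == "sinusoid":
        amp = p.get("amplitude", 0.2)
        lam = p.get("wavelength", 1.0)
        theta = np.radians(p.get("direction_deg", 0.0))
        return lambda e, n: depth + amp * np.sin(
            2 * np.pi * (np.asarray(e) * np.cos(theta) + np.asarray(n) * np.sin(theta)) / lam
        )
    if spec.family == "peak_trough":
        amp = p.get("amplitude", 1.0)
        w = p.get("width", 1.0)
        return lambda e, n: depth + amp * (np.asarray(n) / w) * np.exp(
            -((np.asarray(e) / w) ** 2 + (np.asarray(n) / w) ** 2)
        )
    return None  # noise_field has no closed form


def generate(spec: TerrainSpec) -> TriangleMesh:
    """Generate a triangulated synthetic terrain from a spec.

    Deterministic: identical spec + seed gives byte-identical meshes.
    The analytic height function (where one exists) is attached as
    ``mesh.metadata["height_fn"]`` and the spec as ``["terrain_spec"]``.
    """
    rng = np.random.default_rng(spec.seed)
    e, n = _grid(spec)
    if spec.jitter > 0:
        # interior-only jitter keeps the convex hull rectangular
        half_e, half_n = spec.extent[0] / 2, spec.extent[1] / 2
        interior = (
            (np.abs(e) < half_e - spec.resolution / 2)
            & (np.abs(n) < half_n - spec.resolution / 2)
        )
        e = e + interior * rng.uniform(-spec.jitter, spec.jitter, e.shape) * spec.resolution
        n = n + interior * rng.uniform(-spec.jitter, spec.jitter, n.shape) * spec.resolution
    fn = _height_function(spec)
    if fn is not None:
        z = fn(e, n)
    else:
        z = _correlated_noise(spec, e, rng)
    mesh = delaunay_triangulate(np.column_stack([e, n, z]))
    mesh.metadata["terrain_spec"] = spec
    if fn is not None:
        mesh.metadata["height_fn"] = fn
    return mesh


def _correlated_noise(spec: TerrainSpec, e_flat: np.ndarray, rng) -> np.ndarray:
    """Zero-mean Gaussian field with approximate correlation length.

    White noise on the grid smoothed by a Gaussian kernel of scale
    ``correlation_length`` and rescaled to standard deviation ``sigma``.
    """
    from scipy.ndimage import gaussian_filter

    sigma = spec.params.get("sigma", 0.05)
    corr = spec.params.get("correlation_length", 0.2)
    half_e, half_n = spec.extent[0] / 2, spec.extent[1] / 2
    n_e = len(np.arange(-half_e, half_e + spec.resolution / 2, spec.resolution))
    n_n = len(np.arange(-half_n, half_n + spec.resolution / 2, spec.resolution))
    white = rng.standard_normal((n_e, n_n))
    smooth = gaussian_filter(white, sigma=corr / spec.resolution, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth * (sigma / sd)
    return smooth.ravel() + spec.params.get("depth", 0.0)


def add_vertex_noise(mesh: TriangleMesh, sigma: float, seed: int = 0) -> TriangleMesh:
    """Perturb vertical coordinates with i.i.d. zero-mean Gaussian noise.

    Emulates reconstruction noise from feature-localisation and
    calibration uncertainty.  ``sigma=0`` returns an identical mesh;
    the same seed reproduces the same perturbation.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    vertices = mesh.vertices.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        vertices[:, 2] += rng.normal(0.0, sigma, len(vertices))
    return TriangleMesh(
        vertices=vertices,
        triangles=mesh.triangles.copy(),
        metadata={k: v for k, v in mesh.metadata.items() if k != "height_fn"},
    )


def flat(extent=(6.0, 6.0), resolution=0.05, depth=0.0, **kw) -> TriangleMesh:
    return generate(TerrainSpec("flat", extent, resolution, {"depth": depth}, **kw))


def inclined(slope_deg=30.0, facing_deg=0.0, extent=(6.0, 6.0), resolution=0.05,
             depth=0.0, **kw) -> TriangleMesh:
    return generate(TerrainSpec(
        "inclined", extent, resolution,
        {"slope_deg": slope_deg, "facing_deg": facing_deg, "depth": depth}, **kw))


def sinusoid(amplitude=0.2, wavelength=1.0, direction_deg=0.0, extent=(6.0, 6.0),
             resolution=0.05, depth=0.0, **kw) -> TriangleMesh:
    return generate(TerrainSpec(
        "sinusoid", extent, resolution,
        {"amplitude": amplitude, "wavelength": wavelength,
         "direction_deg": direction_deg, "depth": depth}, **kw))


def peak_trough(amplitude=1.0, width=1.0, extent=(6.0, 6.0), resolution=0.05,
                depth=0.0, **kw) -> TriangleMesh:
    return generate(TerrainSpec(
        "peak_trough", extent, resolution,
        {"amplitude": amplitude, "width": width, "depth": depth}, **kw))


def noise_field(sigma=0.05, correlation_length=0.2, extent=(6.0, 6.0),
                resolution=0.05, depth=0.0, seed=0, **kw) -> TriangleMesh:
    return generate(TerrainSpec(
        "noise_field", extent, resolution,
        {"sigma": sigma, "correlation_length": correlation_length, "depth": depth},
        seed=seed, **kw))
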