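"""Regenerate the synthetic material/spectrum tables packaged under pcct/data.

The packaged curves are *synthetic*: a two-term parametric model
(photoelectric ~ E^-3 plus a Klein-Nishina-shaped Compton term) fitted to a
few approximate anchor values of mass attenuation per material.  They stand
in for measured NIST tables so the whole pipeline ships as plain text and
runs offline.  The tables are inputs to the simulator, not ground truth.

Run from the repository root:

    python scripts/make_data_tables.py
"""
from __future__ import annotations

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "pcct" / "data"

# (density g/cm^3, mu/rho anchors in cm^2/g at 30, 60, 100 keV)
MATERIALS = {
    "water": (1.000, (0.3756, 0.2059, 0.1707)),
    "air": (0.0012, (0.3538, 0.1875, 0.1541)),
    "soft_tissue": (1.060, (0.3714, 0.2048, 0.1693)),
    "adipose": (0.950, (0.3056, 0.1974, 0.1688)),
    "brain_gray_matter": (1.045, (0.3684, 0.2042, 0.1692)),
    "brain_white_matter": (1.041, (0.3656, 0.2040, 0.1695)),
    "blood": (1.060, (0.3780, 0.2058, 0.1701)),
    "cortical_bone": (1.920, (1.3310, 0.3148, 0.1855)),
}

# filter materials for the source spectrum (density, anchors as above)
FILTERS = {
    "beryllium": (1.848, (0.1826, 0.1465, 0.1328)),
    "aluminum": (2.699, (1.1280, 0.2778, 0.1704)),
    "copper": (8.960, (10.920, 1.5930, 0.4584)),
}

ANCHOR_KEV = np.array([30.0, 60.0, 100.0])


def klein_nishina(energy_kev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section (arbitrary units) vs photon energy."""
    k = np.asarray(energy_kev, dtype=float) / 511.0
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
    t2 = np.log(1 + 2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return t1 + t2 + t3


def fit_two_term(anchors: tuple[float, float, float]) -> tuple[float, float]:
    """Least-squares (a, b) for mu/rho(E) = a*(60/E)^3 + b*KN(E)/KN(60)."""
    pe = (60.0 / ANCHOR_KEV) ** 3
    kn = klein_nishina(ANCHOR_KEV) / klein_nishina(np.array([60.0]))[0]
    design = np.stack([pe, kn], axis=1)
    coef, *_ = np.linalg.lstsq(design, np.asarray(anchors), rcond=None)
    return float(coef[0]), float(coef[1])


def mass_attenuation(energy_kev: np.ndarray, a: float, b: float) -> np.ndarray:
    kn = klein_nishina(energy_kev) / klein_nishina(np.array([60.0]))[0]
    return a * (60.0 / energy_kev) ** 3 + b * kn


def write_table(path: pathlib.Path, header: str, energy: np.ndarray, values: np.ndarray) -> None:
    lines = [f"# {line}" for line in header.splitlines()]
    lines += [f"{e:.1f} {v:.6e}" for e, v in zip(energy, values)]
    path.write_text("\n".join(lines) + "\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    grid = np.arange(10.0, 151.0, 1.0)

    for name, (density, anchors) in MATERIALS.items():
        a, b = fit_two_term(anchors)
        mu_rho = mass_attenuation(grid, a, b)
        header = (
            f"synthetic mass attenuation table for {name}\n"
            f"two-term parametric fit (photoelectric + Klein-Nishina) to anchor values\n"
            f"density_g_cm3: {density}\n"
            "columns: energy_keV  mu_over_rho_cm2_g"
        )
        write_table(OUT / f"matten_{name}_synthetic.txt", header, grid, mu_rho)

    # 120 kVp bremsstrahlung (Kramers photon fluence) through Be/Al/Cu filtration
    spec_grid = np.arange(12.0, 121.0, 1.0)
    fluence = np.clip(120.0 - spec_grid, 0.0, None) / spec_grid
    thickness_cm = {"beryllium": 0.08, "aluminum": 0.10, "copper": 0.011}
    for name, (density, anchors) in FILTERS.items():
        a, b = fit_two_term(anchors)
        mu = mass_attenuation(spec_grid, a, b) * density
        fluence = fluence * np.exp(-mu * thickness_cm[name])
    fluence = fluence / fluence.sum()
    header = (
        "synthetic 120 kVp x-ray source spectrum\n"
        "Kramers-law bremsstrahlung filtered by 0.8 mm Be, 1.0 mm Al, 0.11 mm Cu\n"
        "columns: energy_keV  relative_photon_fluence"
    )
    write_table(OUT / "spectrum_120kvp_synthetic.txt", header, spec_grid, fluence)
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
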