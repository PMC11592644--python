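"""Regenerate the packaged amino-acid descriptor tables.

Writes one CSV per descriptor set into ``src/acepep/data/descriptors/`` plus a
``registry.json`` manifest.  Two tables carry real published values:

* ``One-hot`` — exact by definition (20 indicator columns).
* ``Z-scales`` — the five Sandberg et al. (1998) principal-property scales.

Every other set is a dimensionality-correct SYNTHETIC stand-in (flagged
``synthetic: true`` in the manifest and ``_synthetic`` in its filename): a
seeded orthogonal projection of a classical amino-acid property compilation
(Kyte–Doolittle hydropathy, average residue mass, Zamyatnin volume, Grantham
polarity, isoelectric point, net charge, aromatic/aliphatic flags, H-bond
donor/acceptor counts, Chou–Fasman helix and sheet propensities), z-scored per
column.  The stand-ins reproduce the shape and statistical character of the
published descriptor families without claiming their exact numbers.

The registry is table-driven, so a table can be replaced by dropping in a CSV
with the same layout and editing registry.json — no code changes required.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "acepep" / "data"

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Sandberg et al. 1998, J. Med. Chem. 41:2481 — five z-scales per residue.
Z_SCALES = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
}

# Classical property compilation used to build the synthetic stand-ins.
# Columns: KD hydropathy, residue mass, volume (A^3), Grantham polarity, pI,
# net charge (pH 7), aromatic, aliphatic, HB donors, HB acceptors,
# Chou-Fasman P(alpha), P(beta).
PROPERTIES = {
    "A": (1.8, 71.08, 88.6, 8.1, 6.00, 0.0, 0.0, 1.0, 0, 0, 1.42, 0.83),
    "C": (2.5, 103.14, 108.5, 5.5, 5.07, 0.0, 0.0, 0.0, 1, 1, 0.70, 1.19),
    "D": (-3.5, 115.09, 111.1, 13.0, 2.77, -1.0, 0.0, 0.0, 0, 4, 1.01, 0.54),
    "E": (-3.5, 129.12, 138.4, 12.3, 3.22, -1.0, 0.0, 0.0, 0, 4, 1.51, 0.37),
    "F": (2.8, 147.18, 189.9, 5.2, 5.48, 0.0, 1.0, 0.0, 0, 0, 1.13, 1.38),
    "G": (-0.4, 57.05, 60.1, 9.0, 5.97, 0.0, 0.0, 0.0, 0, 0, 0.57, 0.75),
    "H": (-3.2, 137.14, 153.2, 10.4, 7.59, 0.1, 0.5, 0.0, 1, 1, 1.00, 0.87),
    "I": (4.5, 113.16, 166.7, 5.2, 6.02, 0.0, 0.0, 1.0, 0, 0, 1.08, 1.60),
    "K": (-3.9, 128.17, 168.6, 11.3, 9.74, 1.0, 0.0, 0.0, 1, 0, 1.16, 0.74),
    "L": (3.8, 113.16, 166.7, 4.9, 5.98, 0.0, 0.0, 1.0, 0, 0, 1.21, 1.30),
    "M": (1.9, 131.19, 162.9, 5.7, 5.74, 0.0, 0.0, 0.5, 0, 1, 1.45, 1.05),
    "N": (-3.5, 114.10, 114.1, 11.6, 5.41, 0.0, 0.0, 0.0, 2, 2, 0.67, 0.89),
    "P": (-1.6, 97.12, 112.7, 8.0, 6.30, 0.0, 0.0, 0.0, 0, 0, 0.57, 0.55),
    "Q": (-3.5, 128.13, 143.8, 10.5, 5.65, 0.0, 0.0, 0.0, 2, 2, 1.11, 1.10),
    "R": (-4.5, 156.19, 173.4, 10.5, 10.76, 1.0, 0.0, 0.0, 4, 0, 0.98, 0.93),
    "S": (-0.8, 87.08, 89.0, 9.2, 5.68, 0.0, 0.0, 0.0, 1, 1, 0.77, 0.75),
    "T": (-0.7, 101.10, 116.1, 8.6, 5.60, 0.0, 0.0, 0.0, 1, 1, 0.83, 1.19),
    "V": (4.2, 99.13, 140.0, 5.9, 5.96, 0.0, 0.0, 1.0, 0, 0, 1.06, 1.70),
    "W": (-0.9, 186.21, 227.8, 5.4, 5.89, 0.0, 1.0, 0.0, 1, 0, 1.08, 1.37),
    "Y": (-1.3, 163.18, 193.6, 6.2, 5.66, 0.0, 1.0, 0.0, 1, 1, 0.69, 1.47),
}

# (name, n_features, pattern tags, filename stem, synthetic?, source note)
G, E, H, S, C = "geometrical", "electronic", "hydrophobic", "steric", "composition"

SETS = [
    ("One-hot", 20, [C] * 20, "one_hot", False,
     "Indicator encoding of residue identity (exact by definition)."),
    ("Z-scales", 5, [H, S, E, E, E], "z_scales", False,
     "Sandberg et al. 1998 five principal property scales (published values)."),
    ("VHSE", 8, [H, H, S, S, E, E, E, E], "vhse8_synthetic", True,
     "Synthetic stand-in with the dimensionality of the published VHSE scales."),
    ("FASGAI", 6, [H, H, H, S, C, C], "fasgai6_synthetic", True,
     "Synthetic stand-in with the dimensionality of the published FASGAI vectors."),
    ("ST-scales", 8, [G] * 8, "st_scales8_synthetic", True,
     "Synthetic stand-in with the dimensionality of the published ST-scales."),
    ("VSW", 7, [G, G, G, G, E, E, E], "vsw7_synthetic", True,
     "Synthetic stand-in; 7 features so that VSW+Lin contribute 10 jointly."),
    ("Lin", 3, [E, C, C], "lin3_synthetic", True,
     "Synthetic stand-in for Lin's scales; 3 features so that VSW+Lin total 10."),
    ("MS-WHIM", 3, [G, G, E], "ms_whim3_synthetic", True,
     "Synthetic stand-in with the dimensionality of the published MS-WHIM scores."),
    ("ISA-ECI", 2, [E, S], "isa_eci2_synthetic", True,
     "Synthetic stand-in (isotropic surface area / electronic charge index pair)."),
    ("VSTV", 2, [S, G], "vstv2_synthetic", True,
     "Synthetic two-feature stand-in."),
    ("HESE", 6, [H, E, S, E, H, G], "hese6_synthetic", True,
     "Synthetic six-feature stand-in."),
    ("T-scales", 5, [G, G, E, S, C], "t_scales5_synthetic", True,
     "Synthetic stand-in with the dimensionality of the published T-scales."),
    ("Kidera", 10, [G, G, H, S, E, E, C, G, H, S], "kidera10_synthetic", True,
     "Synthetic stand-in with the dimensionality of the Kidera factors."),
    ("BLOSUM-PC", 10, [C, C, E, E, G, G, H, H, S, S], "blosum_pc10_synthetic", True,
     "Synthetic stand-in for BLOSUM-matrix principal components."),
    ("ProtFP", 8, [G, E, H, S, C, G, E, H], "protfp8_synthetic", True,
     "Synthetic stand-in with the dimensionality of the ProtFP descriptors."),
    ("Georgiev-PC", 12, [G, E, H, S, C, G, E, H, S, C, G, E], "georgiev_pc12_synthetic", True,
     "Synthetic stand-in for the leading Georgiev BLOSUM-indices components."),
    ("DPPS", 10, [E, E, H, H, S, S, G, G, C, C], "dpps10_synthetic", True,
     "Synthetic stand-in with the dimensionality of the DPPS descriptors."),
    ("Atchley", 5, [H, S, G, E, C], "atchley5_synthetic", True,
     "Synthetic stand-in with the dimensionality of the Atchley factors."),
    ("Cruciani-PC", 3, [H, E, S], "cruciani_pc3_synthetic", True,
     "Synthetic stand-in with the dimensionality of the Cruciani properties."),
    ("PhysChem", 12, [H, S, G, E, E, C, G, H, S, E, G, C], "physchem12_synthetic", True,
     "Synthetic twelve-feature physicochemical compilation."),
    ("Sneath", 4, [C, G, E, S], "sneath4_synthetic", True,
     "Synthetic stand-in with the dimensionality of the Sneath vectors."),
    ("Zimmerman", 6, [E, H, S, G, C, E], "zimmerman6_synthetic", True,
     "Synthetic six-feature stand-in (Zimmerman-style property set)."),
]


def property_matrix() -> np.ndarray:
    m = np.array([PROPERTIES[r] for r in RESIDUES], dtype=float)
    m = (m - m.mean(axis=0)) / m.std(axis=0)
    return m


def synthetic_table(name: str, d: int, base: np.ndarray) -> np.ndarray:
    """Seeded orthogonal projection of the property compilation to d columns."""
    p = base.shape[1]
    # stable per-name seed, independent of PYTHONHASHSEED
    seed = int.from_bytes(name.encode(), "little") % (2**31)
    rng = np.random.default_rng(seed)
    cols = []
    while len(cols) * p < d + p:  # enough orthogonal columns
        q, _ = np.linalg.qr(rng.standard_normal((p, p)))
        cols.append(q)
    proj = np.concatenate(cols, axis=1)[:, :d]
    tab = base @ proj
    tab = (tab - tab.mean(axis=0)) / tab.std(axis=0)
    return np.round(tab, 3)


def main() -> None:
    desc_dir = OUT / "descriptors"
    desc_dir.mkdir(parents=True, exist_ok=True)
    base = property_matrix()
    manifest = []
    for name, d, tags, stem, synthetic, source in SETS:
        assert len(tags) == d, name
        if name == "One-hot":
            tab = np.eye(20)
            feats = [f"is_{r}" for r in RESIDUES]
        elif name == "Z-scales":
            tab = np.array([Z_SCALES[r] for r in RESIDUES])
            feats = [f"z{i + 1}" for i in range(5)]
        else:
            tab = synthetic_table(name, d, base)
            prefix = stem.split("_synthetic")[0].rstrip("0123456789").rstrip("_")
            feats = [f"{prefix}{i + 1}" for i in range(d)]
        path = desc_dir / f"{stem}.csv"
        with path.open("w") as fh:
            fh.write("residue," + ",".join(feats) + "\n")
            for i, r in enumerate(RESIDUES):
                row = ",".join(f"{v:g}" for v in tab[i])
                fh.write(f"{r},{row}\n")
        manifest.append(
            {
                "name": name,
                "file": f"descriptors/{stem}.csv",
                "n_features": d,
                "pattern_tags": tags,
                "synthetic": synthetic,
                "source": source,
            }
        )
    with (OUT / "registry.json").open("w") as fh:
        json.dump(manifest, fh, indent=1)
    print(f"wrote {len(manifest)} descriptor sets to {desc_dir}")


if __name__ == "__main__":
    main()
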