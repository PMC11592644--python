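[
 {
  "name": "One-hot",
  "file": "descriptors/one_hot.csv",
  "n_features": 20,
  "pattern_tags": [
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition",
   "composition"
  ],
  "synthetic": false,
  "source": "Indicator encoding of residue identity (exact by definition)."
 },
 {
  "name": "Z-scales",
  "file": "descriptors/z_scales.csv",
  "n_features": 5,
  "pattern_tags": [
   "hydrophobic",
   "steric",
   "electronic",
   "electronic",
   "electronic"
  ],
  "synthetic": false,
  "source": "Sandberg et al. 1998 five principal property scales (published values)."
 },
 {
  "name": "VHSE",
  "file": "descriptors/vhse8_synthetic.csv",
  "n_features": 8,
  "pattern_tags": [
   "hydrophobic",
   "hydrophobic",
   "steric",
   "steric",
   "electronic",
   "electronic",
   "electronic",
   "electronic"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the published VHSE scales."
 },
 {
  "name": "FASGAI",
  "file": "descriptors/fasgai6_synthetic.csv",
  "n_features": 6,
  "pattern_tags": [
   "hydrophobic",
   "hydrophobic",
   "hydrophobic",
   "steric",
   "composition",
   "composition"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the published FASGAI vectors."
 },
 {
  "name": "ST-scales",
  "file": "descriptors/st_scales8_synthetic.csv",
  "n_features": 8,
  "pattern_tags": [
   "geometrical",
   "geometrical",
   "geometrical",
   "geometrical",
   "geometrical",
   "geometrical",
   "geometrical",
   "geometrical"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the published ST-scales."
 },
 {
  "name": "VSW",
  "file": "descriptors/vsw7_synthetic.csv",
  "n_features": 7,
  "pattern_tags": [
   "geometrical",
   "geometrical",
   "geometrical",
   "geometrical",
   "electronic",
   "electronic",
   "electronic"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in; 7 features so that VSW+Lin contribute 10 jointly."
 },
 {
  "name": "Lin",
  "file": "descriptors/lin3_synthetic.csv",
  "n_features": 3,
  "pattern_tags": [
   "electronic",
   "composition",
   "composition"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in for Lin's scales; 3 features so that VSW+Lin total 10."
 },
 {
  "name": "MS-WHIM",
  "file": "descriptors/ms_whim3_synthetic.csv",
  "n_features": 3,
  "pattern_tags": [
   "geometrical",
   "geometrical",
   "electronic"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the published MS-WHIM scores."
 },
 {
  "name": "ISA-ECI",
  "file": "descriptors/isa_eci2_synthetic.csv",
  "n_features": 2,
  "pattern_tags": [
   "electronic",
   "steric"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in (isotropic surface area / electronic charge index pair)."
 },
 {
  "name": "VSTV",
  "file": "descriptors/vstv2_synthetic.csv",
  "n_features": 2,
  "pattern_tags": [
   "steric",
   "geometrical"
  ],
  "synthetic": true,
  "source": "Synthetic two-feature stand-in."
 },
 {
  "name": "HESE",
  "file": "descriptors/hese6_synthetic.csv",
  "n_features": 6,
  "pattern_tags": [
   "hydrophobic",
   "electronic",
   "steric",
   "electronic",
   "hydrophobic",
   "geometrical"
  ],
  "synthetic": true,
  "source": "Synthetic six-feature stand-in."
 },
 {
  "name": "T-scales",
  "file": "descriptors/t_scales5_synthetic.csv",
  "n_features": 5,
  "pattern_tags": [
   "geometrical",
   "geometrical",
   "electronic",
   "steric",
   "composition"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the published T-scales."
 },
 {
  "name": "Kidera",
  "file": "descriptors/kidera10_synthetic.csv",
  "n_features": 10,
  "pattern_tags": [
   "geometrical",
   "geometrical",
   "hydrophobic",
   "steric",
   "electronic",
   "electronic",
   "composition",
   "geometrical",
   "hydrophobic",
   "steric"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the Kidera factors."
 },
 {
  "name": "BLOSUM-PC",
  "file": "descriptors/blosum_pc10_synthetic.csv",
  "n_features": 10,
  "pattern_tags": [
   "composition",
   "composition",
   "electronic",
   "electronic",
   "geometrical",
   "geometrical",
   "hydrophobic",
   "hydrophobic",
   "steric",
   "steric"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in for BLOSUM-matrix principal components."
 },
 {
  "name": "ProtFP",
  "file": "descriptors/protfp8_synthetic.csv",
  "n_features": 8,
  "pattern_tags": [
   "geometrical",
   "electronic",
   "hydrophobic",
   "steric",
   "composition",
   "geometrical",
   "electronic",
   "hydrophobic"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the ProtFP descriptors."
 },
 {
  "name": "Georgiev-PC",
  "file": "descriptors/georgiev_pc12_synthetic.csv",
  "n_features": 12,
  "pattern_tags": [
   "geometrical",
   "electronic",
   "hydrophobic",
   "steric",
   "composition",
   "geometrical",
   "electronic",
   "hydrophobic",
   "steric",
   "composition",
   "geometrical",
   "electronic"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in for the leading Georgiev BLOSUM-indices components."
 },
 {
  "name": "DPPS",
  "file": "descriptors/dpps10_synthetic.csv",
  "n_features": 10,
  "pattern_tags": [
   "electronic",
   "electronic",
   "hydrophobic",
   "hydrophobic",
   "steric",
   "steric",
   "geometrical",
   "geometrical",
   "composition",
   "composition"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the DPPS descriptors."
 },
 {
  "name": "Atchley",
  "file": "descriptors/atchley5_synthetic.csv",
  "n_features": 5,
  "pattern_tags": [
   "hydrophobic",
   "steric",
   "geometrical",
   "electronic",
   "composition"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the Atchley factors."
 },
 {
  "name": "Cruciani-PC",
  "file": "descriptors/cruciani_pc3_synthetic.csv",
  "n_features": 3,
  "pattern_tags": [
   "hydrophobic",
   "electronic",
   "steric"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the Cruciani properties."
 },
 {
  "name": "PhysChem",
  "file": "descriptors/physchem12_synthetic.csv",
  "n_features": 12,
  "pattern_tags": [
   "hydrophobic",
   "steric",
   "geometrical",
   "electronic",
   "electronic",
   "composition",
   "geometrical",
   "hydrophobic",
   "steric",
   "electronic",
   "geometrical",
   "composition"
  ],
  "synthetic": true,
  "source": "Synthetic twelve-feature physicochemical compilation."
 },
 {
  "name": "Sneath",
  "file": "descriptors/sneath4_synthetic.csv",
  "n_features": 4,
  "pattern_tags": [
   "composition",
   "geometrical",
   "electronic",
   "steric"
  ],
  "synthetic": true,
  "source": "Synthetic stand-in with the dimensionality of the Sneath vectors."
 },
 {
  "name": "Zimmerman",
  "file": "descriptors/zimmerman6_synthetic.csv",
  "n_features": 6,
  "pattern_tags": [
   "electronic",
   "hydrophobic",
   "steric",
   "geometrical",
   "composition",
   "electronic"
  ],
  "synthetic": true,
  "source": "Synthetic six-feature stand-in (Zimmerman-style property set)."
 }
]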