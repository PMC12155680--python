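{
  "_comment": "Synthetic, illustrative retinal-binding-site pharmacophore model (3 hydrophobic + 1 H-bond acceptor + excluded volumes). Geometry is plausible for a GPCR pocket but is not a reconstruction of any published hypothesis.",
  "features": [
    {"kind": "hydrophobic", "center": [0.0, 0.0, 0.0], "tolerance": 1.5},
    {"kind": "hydrophobic", "center": [-0.5, -3.8, 2.5], "tolerance": 1.5},
    {"kind": "hydrophobic", "center": [-3.3, 3.1, -0.3], "tolerance": 1.5},
    {"kind": "hbond_acceptor", "center": [1.7, -2.2, 4.7], "tolerance": 1.5}
  ],
  "volumes": [
    {"center": [4.0, 2.5, 0.0], "radius": 1.2},
    {"center": [-4.5, -1.0, -2.5], "radius": 1.2},
    {"center": [0.5, 3.0, 3.5], "radius": 1.2}
  ]
}
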