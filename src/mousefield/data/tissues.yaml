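# Default tissue conductivities (S/m) for the five-compartment mouse body
# model, plus the auxiliary materials used by montage operations.
1:
  name: gray_matter
  conductivity_S_per_m: 0.275
2:
  name: csf
  conductivity_S_per_m: 1.654
3:
  name: bone
  conductivity_S_per_m: 0.01
4:
  name: soft_tissue
  conductivity_S_per_m: 0.465
5:
  name: eyeball
  conductivity_S_per_m: 0.5
6:
  name: gel
  conductivity_S_per_m: 0.3
7:
  name: air
  conductivity_S_per_m: 2.5e-14
8:
  name: saline
  conductivity_S_per_m: 1.654
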