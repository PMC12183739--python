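# Flavin-tryptophan radical pair system definition (toy model).
# SYNTHETIC RECONSTRUCTION (non-canonical): the true time-averaged tensors of
# this model are not publicly tabulated. FN5 is the canonical literature DFT
# hyperfine tensor of the flavin N5 nitrogen; all other tensors are
# representative literature-range values, and the unprinted geometry (the
# inter-radical axis, here (1,1,1)/sqrt(3) at 1.5 nm, and the WNE1 Azz
# principal value) was fixed once so that the toy static eigenvalue span
# matches its published value of ~81 MHz. Units: mT, row-major xx..zz,
# flavin frame (z = flavin-plane normal).
name = toy
field_mT = 0.05
k_per_s = 1000000.0
dipolar_mT = -1.028806669e-16 -0.5491358025 -0.5491358025 -0.5491358025 -1.028806669e-16 -0.5491358025 -0.5491358025 -0.5491358025 -1.028806669e-16
nucleus = FN5 1 3 -0.0989 0.0039 0 0.0039 -0.0881 0 0 0 1.7569
nucleus = WNE1 2 3 -0.0931 0 0 0 -0.0842 0 0 0 0.8468
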