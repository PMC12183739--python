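# Flavin-tryptophan radical pair system definition (fourteen model).
# SYNTHETIC RECONSTRUCTION (non-canonical): the true time-averaged tensors of
# this model are not publicly tabulated. FN5 is the canonical literature DFT
# hyperfine tensor of the flavin N5 nitrogen; all other tensors are
# representative literature-range values, and the unprinted geometry (the
# inter-radical axis, here (1,1,1)/sqrt(3) at 1.5 nm, and the WNE1 Azz
# principal value) was fixed once so that the toy static eigenvalue span
# matches its published value of ~81 MHz. Units: mT, row-major xx..zz,
# flavin frame (z = flavin-plane normal).
name = fourteen
field_mT = 0.05
k_per_s = 1000000.0
dipolar_mT = -1.028806669e-16 -0.5491358025 -0.5491358025 -0.5491358025 -1.028806669e-16 -0.5491358025 -0.5491358025 -0.5491358025 -1.028806669e-16
nucleus = FN5 1 3 -0.0989 0.0039 0 0.0039 -0.0881 0 0 0 1.7569
nucleus = WNE1 2 3 -0.0931 0 0 0 -0.0842 0 0 0 0.8468
nucleus = FN10 1 3 -0.019 0 0 0 -0.0048 0 0 0 0.6046
nucleus = WHE1 2 2 -0.85 0 0 0 -0.4 0 0 0 -0.35
nucleus = FH6 1 2 -0.43 0 0 0 -0.37 0 0 0 -0.27
nucleus = WHB1 2 2 1.2 0 0 0 1.25 0 0 0 1.35
nucleus = FH8a 1 2 0.25 0 0 0 0.26 0 0 0 0.28
nucleus = WHE3 2 2 -0.18 0 0 0 -0.25 0 0 0 -0.48
nucleus = WHB2 2 2 0.4 0 0 0 0.42 0 0 0 0.48
nucleus = WHD1 2 2 -0.15 0 0 0 -0.22 0 0 0 -0.42
nucleus = FH9 1 2 0.1 0 0 0 0.12 0 0 0 0.15
nucleus = WHZ2 2 2 -0.12 0 0 0 -0.18 0 0 0 -0.35
nucleus = WHH2 2 2 -0.1 0 0 0 -0.15 0 0 0 -0.3
nucleus = FH7a 1 2 -0.03 0 0 0 -0.04 0 0 0 -0.05
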