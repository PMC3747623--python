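"""Single-nucleotide mutation spectrum and composition summary.

The spectrum table gives the fraction of called events per directed
substitution with its transition/transversion class; the composition
summary compares base fractions of the complete alignment against the
conserved regions used as the frequency denominator.
"""

import contextmut as cm

block, roster, _ = cm.simulate(cm.SimulationConfig(length=60_000, seed=12))
events = cm.call_mutations([block], roster)

spectrum = cm.spectrum_table(events)
print(spectrum.to_string(index=False))
sums = cm.spectrum_sums(spectrum)
print(f"\ntransitions {sums['transitions']:.3f} + transversions {sums['transversions']:.3f} = 1")
# the simulator applies a uniform per-substitution rate, so the 12
# fractions differ only through base composition and sampling noise

mask = cm.conserved_mask([block], roster)
print("\ncomposition (complete vs conserved):")
print(cm.composition_summary([block], mask, roster).to_string(index=False))

print("\npublished spectra for comparison:")
for species in ("dmel", "hsap"):
    ref = cm.spectrum_table(cm.load_reference_spectrum(species))
    s = cm.spectrum_sums(ref)
    print(f"  {species}: transitions {s['transitions']:.3f}, transversions {s['transversions']:.3f}")
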