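"""Segregate the frontal talker from a five-source cocktail-party mixture.

Five speech-like talkers (target at 0 degrees, maskers at +/-30 and +/-60)
are mixed at 0 dB target-to-masker ratio, passed through the full pipeline
(filterbank, spatially tuned neurons, Poisson spikes, mask reconstruction),
and scored with STOI against the clean spatialized target.
"""

from dataclasses import replace

from bossa import MixtureSpec, default_mixture, segregate, stoi_binaural
from bossa.config import narrowband_demo_config

fs = 20000.0
cfg = narrowband_demo_config()
cfg.filterbank = replace(cfg.filterbank, fs=fs)
hrtf = cfg.build_hrtf()
bank = cfg.build_bank(hrtf=hrtf)

mix, clean = default_mixture(MixtureSpec(tmr_db=0.0, seed=11), hrtf, duration=2.0, fs=fs)
print("mixture: frontal target + 4 maskers at +/-30, +/-60 deg, 0 dB TMR")
print(f"STOI of raw mixture vs clean target:  {stoi_binaural(clean, mix, fs):.3f}")

for kind in ("frmask", "diffmask"):
    out = segregate(mix, replace(cfg, mask_kind=kind), hrtf=hrtf, bank=bank)
    print(f"STOI of {kind:8s} output:             {stoi_binaural(clean, out, fs):.3f}")

print(
    "\nFRMask passes everything the frontal neuron set responds to; DiffMask"
    "\nsubtracts the off-target sets' activity, removing more masker energy"
    "\nbut also more target energy -- STOI penalizes that sparseness even"
    "\nwhere listeners would benefit from the masker suppression."
)
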