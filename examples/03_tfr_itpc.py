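"""Morlet power and inter-trial phase consistency around task events.

Decomposes simulated epochs with the log-spaced wavelet bank, bins power
and ITPC into 100 ms intervals aligned to stimulus disappearance, and
normalizes power to the pre-movement baseline.  The injected ground truth
(beta envelope drop, delta phase reset) should re-emerge in the maps.
"""

import numpy as np

from tempopred import (FilterSpec, OscillatoryTruth, TaskDesign, align,
                       band_window_average, baseline_normalize, build_bank,
                       build_schedule, convolve, filter_continuous, itpc,
                       power_binned, simulate_eeg, standard_layout)
from tempopred.preprocess import epoch

design = TaskDesign(sampling_rate=250)  # reduced rate for a fast example
layout = standard_layout(16)
schedule = build_schedule(design, 60, seed=5)
truth = OscillatoryTruth(beta_suppression=-0.4, delta_kappa=5.0, snr=1.5)
rec = filter_continuous(simulate_eeg(schedule, truth, layout, design, seed=5),
                        FilterSpec())
epochs = epoch(rec, schedule, design)
print(f"{len(epochs)} epochs cut (variable length, event-aligned)")

bank = build_bank(1.0, 40.0, 12, fs=design.sampling_rate)
tfrs, valids = [], []
for e in epochs:
    c, v = convolve(e.data, bank)
    tfrs.append(c)
    valids.append(v)

dis = align(tfrs, valids, [e.events["disappear"] for e in epochs],
            (-350.0, 950.0), design.sampling_rate, bank.freqs)
base = align(tfrs, valids, [e.events["move_on"] for e in epochs],
             (-500.0, -200.0), design.sampling_rate, bank.freqs)

rel = baseline_normalize(power_binned(dis), power_binned(base), "relative")
beta = band_window_average(rel, (13.0, 30.0), (-200.0, 600.0),
                           require_valid=False)
print(f"relative beta power around disappearance: min {beta.min():.2f} "
      f"at channel {layout.labels[int(beta.argmin())]}")
# -> clearly negative over the fronto-central generator: the injected
#    envelope suppression survives filtering, epoching and binning

R = itpc(dis)
delta = band_window_average(R, (1.0, 4.0), (-200.0, 900.0),
                            require_valid=False)
floor = np.sqrt(np.pi) / (2 * np.sqrt(dis.n_trials))
print(f"delta ITPC: max {delta.max():.2f} at "
      f"{layout.labels[int(delta.argmax())]} "
      f"(chance floor for {dis.n_trials} trials ~ {floor:.2f})")
# -> the phase-reset generator drives ITPC far above the Rayleigh floor
#    at posterior sensors
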