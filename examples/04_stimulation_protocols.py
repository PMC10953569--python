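"""Compile electrical and optical stimulation protocols.

Electrical: 1 s trains of 20 Hz biphasic pulses (positive-to-negative,
400 µs per phase).  Optical: 1 s trains of 40 Hz pulses at 20% duty cycle,
one train every 5 s for one minute.
"""

import meakit as mk

elec = mk.PulseTrainSpec(
    pulse_rate_hz=20, train_duration_s=1.0, inter_train_period_s=2.0,
    n_trains=6, mode="biphasic_electrical", phase_us=400, amplitude=700,
)
tl = mk.compile_biphasic(elec, target="stim_site_bottom")
print(f"electrical: {elec.pulses_per_train} pulses/train, "
      f"{tl.n_events} phase events over {tl.total_duration_s:.0f} s")
a, b, level = tl.events[0]
print(f"  first phase: +{level:.0f} mV for {(b - a) * 1e6:.0f} µs")

n_trains = mk.trains_for_duration(total_s=60.0, inter_train_period_s=5.0)
opt = mk.PulseTrainSpec(
    pulse_rate_hz=40, train_duration_s=1.0, inter_train_period_s=5.0,
    n_trains=n_trains, mode="optical", duty_cycle=0.2,
)
tl = mk.compile_optical(opt, target="well_3")
on = tl.events[0][1] - tl.events[0][0]
print(f"optical: {n_trains} trains, {opt.pulses_per_train} pulses/train, "
      f"each on for {on * 1e3:.1f} ms")
print(f"  validation: {mk.validate_timeline(tl)}")

# Pulse counts come straight from floor(rate x duration); the 5 ms on-time
# is duty_cycle / pulse_rate; validation confirms ordering and non-overlap.
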