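# One simulated mote deployment: flat key-value schema, fields as in
# motenet.SimConfig. Unlisted keys keep their defaults.
n_camps: 1
camp_size_range: [12, 12]
study_days: 3
slot_minutes: 2
day_window: ['05:00', '20:00']
base_rate: 0.005          # per dyad-slot detection probability
household_boost: 8.0
kin_boost: 3.0
gregariousness_sd: 0.5
drop_prob: 0.1            # one-directional radio loss
late_frac: 0.15           # share arriving late / leaving early
seed: 1
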