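"""Extract band features from raw windowed signals.

EEG windows become differential-entropy values per (channel, band); a
peripheral channel window becomes eight time/frequency statistics. The same
windowing (3-s windows, 2-s overlap) applies to both streams.
"""

from hatl import WindowSpec, extract_dataset, get_profile
from hatl.simulate import simulate_raw_recording

schema = get_profile("deap")  # 32 EEG channels x 4 bands + 8 x 8 peripheral

eeg = simulate_raw_recording({(4.0, 45.0): 1.0}, fs=128.0, duration_s=10.0,
                             seed=0, n_channels=32,
                             channel_names=schema.eeg_channels)
periph = simulate_raw_recording({(0.5, 10.0): 1.0}, fs=128.0, duration_s=10.0,
                                seed=1, n_channels=8,
                                channel_names=tuple(f"P{i}" for i in range(8)),
                                kind="peripheral")

ds = extract_dataset(eeg, periph, schema, WindowSpec(3.0, 2.0),
                     label=2, subject="s01")
print(f"windows extracted: {ds.n_rows}")
print(f"EEG features per window: {ds.X_eeg.shape[1]} (32 channels x 4 bands)")
print(f"non-EEG features per window: {ds.S_noneeg.shape[1]} (8 channels x 8 stats)")
print(f"first EEG row (differential entropy, nats): {ds.X_eeg[0][:4].round(3)} ...")
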