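"""Wireless-link budget for spike transform coding.

Computes the per-spike and per-channel data rates when transmitting L
compression coefficients per detected spike instead of raw samples.
"""

from spikecodec import data_rate

for L in (64, 8, 4):
    r = data_rate(L)
    print(
        f"L={L:2d}: {r.bits_per_spike:6.0f} bits/spike, "
        f"compression x{r.compression_factor:5.1f}, "
        f"channel rate {r.channel_rate_bps / 1e3:7.2f} kbps, "
        f"{r.channels_supported:4d} channels on a 1 Mbps link"
    )

r = data_rate(4)
print(
    f"\nAt L=4 the spike-coded channel rate is {r.channel_rate_bps / 1e3:.1f} kbps "
    f"against {r.raw_channel_rate_bps / 1e3:.0f} kbps for raw streaming: "
    f"a {100 * r.reduction:.2f}% reduction, supporting "
    f"{r.channels_supported // r.raw_channels_supported}x more channels."
)
print(
    "Each line assumes 10-bit samples, 64-sample spikes, and 4 neurons "
    "firing at 10 spikes/s per channel."
)
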