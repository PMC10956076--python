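"""The spectral-slope E/I baseline, and why it fails at 100 Hz sampling.

The prior method estimates E/I balance from the slope of the log-log
power spectral density between 30 and 50 Hz.  On a 1/f^2 surrogate the
estimator recovers the exponent; on 100 Hz recordings the 30-50 Hz band
touches the Nyquist frequency exactly, and any wider band is refused.
"""

import numpy as np

from eitrack import ei_slope

n, fs = 120_000, 1000.0
freqs = np.fft.rfftfreq(n, 1 / fs)
rng = np.random.default_rng(0)
spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
with np.errstate(divide="ignore"):
    x = np.fft.irfft(spec * np.where(freqs > 0, freqs**-1.0, 0.0), n=n)

print(f"slope of a 1/f^2 surrogate: {ei_slope(x, fs=fs):.2f}  (expected -2)")

try:
    ei_slope(rng.normal(size=4000), fs=100.0, band=(30.0, 55.0))
except ValueError as exc:
    print(f"band (30, 55) Hz at fs = 100 Hz refused: {exc}")

# A more negative slope indicates inhibition-dominant dynamics under the
# prior method's model; the hard Nyquist check mirrors the reason the
# baseline is uninformative for 100 Hz sleep recordings.
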