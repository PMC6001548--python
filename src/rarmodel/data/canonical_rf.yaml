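# Canonical gamma parameters of the fear-conditioned respiration amplitude
# response functions, estimated from the difference between average CS+ and
# CS- responses in a delay-conditioning development data set. The early
# response (ER) peaks shortly before the unconditioned stimulus; the late
# response (LR) peaks at ~10.25 s after CS onset. Amplitude A is left free
# at inversion time; components are peak-normalized when a basis is built.
version: 1
components:
  ER:
    k: 2.57010e+7
    theta: 3.12410e-4
    x0: -8.02434e+3
  LR:
    k: 3.41302
    theta: 1.10734
    x0: 7.58288
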