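# Synthetic voltage-gated channel kinetics (Hodgkin-Huxley form).
#
# This file is a SYNTHETIC transcription: the published kinetics table for
# the interneuron channel set (na_t, na_p, kdrf, kdrf_faster, kdrs, ka) is
# available only as an image and the referenced model-archive entries are
# not bundled, so the parameters below were authored for this package.
# They use standard sigmoid steady states and constant/bell/sigmoid time
# constants, tuned so that the published conductance-density grids
# reproduce the four signature regimes (sag-free hyperpolarization,
# passive +20 pA response, regular spiking at +50 pA, depolarization block
# at +500 pA) on the bundled fixture morphology.  Reversals: E_Na = 50 mV,
# E_K = -77 mV in all simulations.
#
# Gate fields: vhalf/k (mV) give steady state 1/(1+exp(-(V-vhalf)/k));
# k < 0 encodes inactivation.  tau forms (ms):
#   constant: tau0
#   bell:     tau_min + amp / (exp((V-vt)/a) + exp(-(V-vt)/b))
#   sigmoid:  tau_min + amp / (1 + exp((V-vt)/a))

channels:
  na_t:
    reversal: 50.0
    gates:
      m:
        vhalf: -29.0
        k: 6.5
        exponent: 3
        tau: {form: bell, tau_min: 0.04, amp: 0.35, vt: -29.0, a: 16.0, b: 16.0}
      h:
        vhalf: -49.0
        k: -6.5
        exponent: 1
        tau: {form: sigmoid, tau_min: 0.5, amp: 20.0, vt: -45.0, a: 10.0}
  na_p:
    reversal: 50.0
    gates:
      m:
        vhalf: -48.7
        k: 4.4
        exponent: 1
        tau: {form: constant, tau0: 1.0}
  kdrf:
    reversal: -77.0
    gates:
      n:
        vhalf: -22.0
        k: 7.0
        exponent: 4
        tau: {form: bell, tau_min: 1.2, amp: 8.0, vt: -30.0, a: 20.0, b: 20.0}
  kdrf_faster:
    reversal: -77.0
    gates:
      n:
        vhalf: -22.0
        k: 7.0
        exponent: 4
        tau: {form: bell, tau_min: 0.6, amp: 4.5, vt: -30.0, a: 20.0, b: 20.0}
  kdrs:
    reversal: -77.0
    gates:
      n:
        vhalf: -25.0
        k: 10.0
        exponent: 4
        tau: {form: bell, tau_min: 6.0, amp: 50.0, vt: -30.0, a: 25.0, b: 25.0}
  ka:
    reversal: -77.0
    gates:
      a:
        vhalf: -35.0
        k: 10.0
        exponent: 4
        tau: {form: bell, tau_min: 0.4, amp: 1.5, vt: -35.0, a: 20.0, b: 20.0}
      b:
        vhalf: -62.0
        k: -8.0
        exponent: 1
        tau: {form: sigmoid, tau_min: 8.0, amp: 40.0, vt: -55.0, a: 10.0}
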