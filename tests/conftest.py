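import numpy as np
import pytest

from ca1net.config import default_config, load_config

TOY_YAML = """
name: toy
seed: 7
geometry:
  longitudinal_um: 1000.0
  transverse_um: 400.0
  layers: {SO: [0.0, 100.0], SP: [100.0, 150.0], SR: [150.0, 400.0], SLM: [400.0, 550.0]}
cell_types:
  E: {count: 60, layer: SP, is_principal: true, neuron: E}
  I: {count: 20, layer: SP, neuron: I}
afferents:
  AFF: {count: 100, rate_hz: 20.0, layer: SR}
synapse_channels:
  AMPA: {tau1_ms: 0.5, tau2_ms: 3.0, e_rev_mv: 0.0}
  GABAA: {tau1_ms: 0.3, tau2_ms: 5.0, e_rev_mv: -60.0}
  GABAB: {tau1_ms: 25.0, tau2_ms: 100.0, e_rev_mv: -90.0}
axonal_profiles:
  E: {mean_um: 200.0, sd_um: 150.0, extent_um: 600.0, bin_um: 100.0}
  I: {mean_um: 150.0, sd_um: 100.0, extent_um: 500.0, bin_um: 100.0}
  AFF: {mean_um: 300.0, sd_um: 300.0, extent_um: 1000.0, bin_um: 100.0}
neurons:
  E: {e_leak_mv: -63.0, r_in_mohm: 100.0, tau_m_ms: 10.0, v_thresh_mv: -46.0,
      delta_t_mv: 2.0, v_reset_mv: -63.0, t_ref_ms: 2.0, adapt_b_pa: 30.0,
      tau_w_ms: 100.0}
  I: {e_leak_mv: -65.0, r_in_mohm: 150.0, tau_m_ms: 8.0, v_thresh_mv: -45.0,
      delta_t_mv: 1.0, v_reset_mv: -65.0, t_ref_ms: 1.0}
projections:
  E:
    E: {synapses: 600, syn_per_conn: 1, weight_ns: 0.5, channel: AMPA,
        zones: [basal_dendrite]}
    I: {synapses: 1200, syn_per_conn: 2, weight_ns: 1.0, channel: AMPA,
        zones: [soma, proximal_dendrite_SR]}
  I:
    E: {synapses: 2000, syn_per_conn: 5, weight_ns: 1.5, channel: GABAA,
        zones: [soma]}
  AFF:
    E: {synapses: 3000, syn_per_conn: 1, weight_ns: 2.0, channel: AMPA,
        zones: [proximal_dendrite_SR]}
    I: {synapses: 1000, syn_per_conn: 1, weight_ns: 2.0, channel: AMPA,
        zones: [soma]}
"""


@pytest.fixture(scope="session")
def toy_cfg():
    return load_config(TOY_YAML)


@pytest.fixture(scope="session")
def full_cfg():
    return default_config()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
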