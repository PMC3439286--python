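{
  "comment": "MinD/MinE membrane-cycling rate constants of Huang, Meir & Wingreen, PNAS 100 (2003) 12724 ('Dynamic structures in Escherichia coli: spontaneous formation of MinE rings and MinD polar zones'), the parameterization behind the stochastic Min oscillation benchmark. Membrane recruitment of MinD:ATP is cooperative via both membrane-bound MinD and MinDE. Copy numbers correspond to Huang's 1000 MinD/um and 350 MinE/um on a 4.5 um cell. Quantitative Min results depend on this transcription.",
  "sigma_d_um_per_s": 0.025,
  "sigma_dD_um3_per_s": 0.0015,
  "sigma_dE_um3_per_s": 0.093,
  "sigma_e_per_s": 0.7,
  "sigma_adp_atp_per_s": 1.0,
  "D_cytosol_um2_per_s": 2.5,
  "D_membrane_um2_per_s": 0.01,
  "n_mind": 4500,
  "n_mine": 1575
}
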