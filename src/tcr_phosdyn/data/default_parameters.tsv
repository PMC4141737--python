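# Reconstructed default parameter table for the TCR/CD28 model.
# These are NOT the original study's fitted values (that table is not
# reproducible here); they are order-of-magnitude defaults tuned so the
# model's directional behaviors hold.  Units: unimolecular constants in 1/s;
# bimolecular constants in events/s per reactant pair (copy-number units,
# single well-mixed volume); copy numbers (N_*) in molecules per cell,
# deliberately scaled to ~100 per species for cheap Monte Carlo averaging.
# class: reconstructed (default) | fitted (refit by the fitting module).
name	value	class	lower	upper
k_lig_on	0.01	reconstructed	1e-4	1
k_lckcd28_on	0.005	reconstructed	1e-4	1
k_lckcd28_off	0.1	reconstructed	1e-3	10
k_nckcd3e_on	0.005	reconstructed	1e-4	1
k_nckcd3e_off	0.05	reconstructed	1e-3	10
k_nckwas_on	0.005	reconstructed	1e-4	1
k_nckwas_off	0.05	reconstructed	1e-3	10
k_y394	0.002	reconstructed	1e-5	0.1
k_y394_off	0.05	reconstructed	1e-3	1
k_itam	0.003	reconstructed	1e-5	0.1
k_y171	0.001	reconstructed	1e-5	0.1
k_site_off	0.01	reconstructed	1e-4	1
k_zap_on	0.01	reconstructed	1e-4	1
k_zap_off	0.1	reconstructed	1e-3	10
k_y493	0.005	reconstructed	1e-5	0.1
k_y292	0.0005	reconstructed	1e-5	0.1
k_lat	0.0015	reconstructed	1e-5	0.1
k_lat2	0.001	reconstructed	1e-5	0.1
k_lcp2	0.003	reconstructed	1e-5	0.1
k_grap2_on	0.005	reconstructed	1e-4	1
k_grap2_off	0.05	reconstructed	1e-3	10
k_g2l_on	0.005	reconstructed	1e-4	1
k_g2l_off	0.05	reconstructed	1e-3	10
k_ncklcp2_on	0.005	reconstructed	1e-4	1
k_ncklcp2_off	0.05	reconstructed	1e-3	10
k_was	0.005	reconstructed	1e-5	0.1
k_plc_on	0.01	reconstructed	1e-4	1
k_plc_off	0.05	reconstructed	1e-3	10
k_y783	0.006	reconstructed	1e-5	0.1
k_y771	0.003	reconstructed	1e-5	0.1
k_pag1	0.0002	reconstructed	1e-6	0.01
k_slow_off	0.01	reconstructed	1e-4	1
k_basal_on	0.01	reconstructed	1e-4	1
k_csk_on	0.005	reconstructed	1e-4	1
k_csk_off	0.1	reconstructed	1e-3	10
k_y505	0.003	reconstructed	1e-5	0.1
k_y505_off	0.08	reconstructed	1e-4	1
k_rasa_on	0.005	reconstructed	1e-4	1
k_rasa_off	0.1	reconstructed	1e-3	10
k_y566	0.008	reconstructed	1e-5	0.1
k_shp1	0.006	reconstructed	1e-5	0.1
N_CD28	120	reconstructed	0	1e6
N_CD3E	120	reconstructed	0	1e6
N_CD3G	120	reconstructed	0	1e6
N_LCK	150	reconstructed	0	1e6
N_ZAP70	150	reconstructed	0	1e6
N_LAT	150	reconstructed	0	1e6
N_GRAP2	100	reconstructed	0	1e6
N_LCP2	120	reconstructed	0	1e6
N_NCK1	120	reconstructed	0	1e6
N_WAS	100	reconstructed	0	1e6
N_PLCG1	100	reconstructed	0	1e6
N_PTPN6	100	reconstructed	0	1e6
N_PAG1	120	reconstructed	0	1e6
N_CSK	100	reconstructed	0	1e6
N_DOK1	80	reconstructed	0	1e6
N_DOK2	80	reconstructed	0	1e6
N_RASA1	80	reconstructed	0	1e6
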