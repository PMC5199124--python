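name	value	units	description	source
d1	0.13	uM	IP3R IP3-activation equilibrium constant	De Young & Keizer 1992 / Li & Rinzel 1994
d5	0.08234	uM	IP3R calcium-activation equilibrium constant	De Young & Keizer 1992 / Li & Rinzel 1994
dinh	0.4	uM	IP3R calcium-inactivation equilibrium constant	adapted from De Young & Keizer 1992 (d2), tuned for transient shape
a2	0.2	1/(uM*s)	IP3R inactivation gating rate	De Young & Keizer 1992 / Li & Rinzel 1994
v_rel	3.0	1/s	maximal IP3R channel flux rate	adapted from Li & Rinzel 1994 (v1)
v_serca	1.5	uM/s	SERCA maximal pump rate	adapted from Li & Rinzel 1994 (v3)
k_serca	0.1	uM	SERCA half-saturation constant	Li & Rinzel 1994 (k3)
k_plc	0.01	1/s	receptor/PLC activation gain per uM ATP	chosen, biologically reasonable range
k_r	0.003	1/s	receptor desensitization rate	chosen, biologically reasonable range
k_plc_deg	0.2	1/s	PLC deactivation rate	chosen, biologically reasonable range
v_ip3	0.2	uM/s	maximal IP3 production rate	adapted from Lemon et al 2003
k_hill	0.3	PLC units	PLC half-saturation of IP3 production	chosen, biologically reasonable range
n_hill	2.0	dimensionless	Hill coefficient of IP3 production	chosen, biologically reasonable range
k_ip3_deg	0.05	1/s	IP3 linear degradation rate	adapted from Lemon et al 2003
c1	0.185	dimensionless	ER:cytosol volume ratio	De Young & Keizer 1992 / Li & Rinzel 1994
c0	2.0	uM	total conserved calcium (cytosolic equivalent)	Li & Rinzel 1994
b_buf	0.1	dimensionless	free fraction of cytosolic calcium (single buffer factor)	chosen, biologically reasonable range
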