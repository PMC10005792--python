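brand,kinds,temperature_k,c_s_dd,c_s_dd_unc,c_s_dd_fixed,tau_s,tau_s_unc,tau_s_fixed,c_i_dd,c_i_dd_unc,c_i_dd_fixed,tau_i,tau_i_unc,tau_i_fixed,c_f_dd,c_f_dd_unc,c_f_dd_fixed,tau_f,tau_f_unc,tau_f_fixed,a,a_unc,a_fixed
Haribo,bear|phantasia,298,1.46e8,6.1e7,0,2.43e-6,5.2e-7,0,1.00e9,1.2e7,0,4.83e-7,3.9e-8,0,1.25e9,3.2e8,0,5.21e-8,2.7e-9,0,27.0,3.2,0
Haribo,bear|phantasia,323,1.46e8,6.1e7,0,2.43e-6,,1,8.02e8,4.3e7,0,3.49e-7,2.6e-8,0,1.25e9,3.2e8,0,5.21e-8,2.7e-9,0,27.0,,1
Haribo,balla-apple,298,1.46e8,6.1e7,0,1.64e-6,6.9e-8,0,5.20e8,3.3e7,0,3.97e-7,2.9e-8,0,1.25e9,3.2e8,0,5.21e-8,2.7e-9,0,40.6,5.3,0
Haribo,balla-apple,323,1.46e8,6.1e7,0,1.50e-6,5.7e-8,0,4.12e8,2.9e7,0,3.00e-7,2.8e-8,0,1.25e9,3.2e8,0,5.21e-8,2.7e-9,0,40.6,,1
Haribo,balla-raspberry,298,1.46e8,6.1e7,0,1.76e-6,1.3e-7,0,7.86e8,3.9e7,0,4.34e-7,3.0e-8,0,1.25e9,3.2e8,0,5.21e-8,2.7e-9,0,37.8,3.3,0
Haribo,balla-raspberry,323,1.46e8,6.1e7,0,1.37e-6,3.6e-8,0,1.78e8,2.1e7,0,2.74e-7,4.2e-8,0,1.02e9,3.4e8,0,5.21e-8,2.7e-9,0,37.8,,1
Haribo,tropifruity|color-rado,298,1.46e8,6.1e7,0,1.92e-6,5.0e-8,0,7.08e8,1.6e7,0,4.17e-7,1.3e-8,0,1.25e9,3.2e8,0,5.21e-8,2.7e-9,0,33.1,3.7,0
Haribo,tropifruity|color-rado,323,1.46e8,6.1e7,0,1.20e-6,5.8e-8,0,3.61e8,2.2e7,0,3.66e-7,3.3e-8,0,1.25e9,3.2e8,0,5.21e-8,2.7e-9,0,33.1,,1
Vidal,coke|fish|pizza,323,1.46e8,,1,1.53e-6,2.8e-8,0,6.98e8,6.9e7,0,2.53e-7,1.6e-8,0,1.25e9,,1,3.55e-8,6.3e-9,0,25.6,1.2,0
Vidal,cherry,323,1.16e7,3.1e6,0,2.55e-6,5.3e-7,0,1.38e8,1.7e7,0,3.45e-7,2.4e-8,0,9.11e8,3.1e7,0,5.61e-8,2.4e-9,0,38.4,2.2,0
Vidal,roll,323,1.46e8,,1,1.26e-6,3.0e-8,0,4.90e8,2.0e8,0,9.32e-8,2.6e-8,0,1.25e9,,1,9.68e-9,6.1e-9,0,15.1,0.8,0
Vidal,watermelon,323,2.94e7,8.8e7,0,2.44e-6,4.7e-7,0,1.64e8,2.5e7,0,4.27e-7,8.8e-8,0,8.79e8,6.6e7,0,4.39e-8,6.7e-9,0,35.0,3.3,0
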