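# SYNTHETIC reference compound panel for LogD vs Log K_in efflux profiling.
# Compound names and LogD (pH 7.4) values are literature-plausible; the
# kin_ul_s_g values are constructed on a reference passive-diffusion line
# (log10 Kin[mL/s/g] = 0.8*LogD - 2.1, small scatter) so the panel is
# internally consistent. R123's LogD/K_in pair is the measured value this
# package's kinetics module reproduces; it sits ~3 log units below the
# passive line. Edit or replace this file with your laboratory's panel.
name,logd,kin_ul_s_g,known_class
antipyrine,0.38,17.95,passive
caffeine,-0.07,5.808,passive
ethanol,-0.31,5.649,passive
nicotine,0.93,38.37,passive
propranolol,1.34,110.2,passive
diazepam,2.84,1355,passive
theophylline,-0.05,7.586,passive
phenytoin,2.26,444.6,passive
R123,1.51,0.12,efflux
quinidine,2.41,2.128,efflux
loperamide,2.95,0.5754,efflux
digoxin,1.26,0.1282,efflux
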