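lab,cohort,genotype,sex,p_value,direction
lab1,1,Canton-S,F,0.07,
lab1,2,Canton-S,F,3e-5,AL
lab1,3,Canton-S,F,6e-10,AL
lab1,4,Canton-S,F,0.1,
lab2,1,Canton-S,F,0.4,
lab2,2,Canton-S,F,8e-15,DR
lab2,3,Canton-S,F,0.02,
lab2,4,Canton-S,F,6e-6,AL
lab1,1,Canton-S,M,0.02,
lab1,2,Canton-S,M,0.5,
lab1,3,Canton-S,M,2e-9,DR
lab1,4,Canton-S,M,0.06,
lab2,1,Canton-S,M,0.1,
lab2,2,Canton-S,M,5e-17,DR
lab2,3,Canton-S,M,0.004,
lab2,4,Canton-S,M,7e-4,DR
lab1,1,Oregon-R,F,1e-5,DR
lab1,2,Oregon-R,F,0.07,
lab1,3,Oregon-R,F,0.003,
lab1,4,Oregon-R,F,0.8,
lab2,1,Oregon-R,F,0.004,
lab2,2,Oregon-R,F,0.03,
lab2,3,Oregon-R,F,0.01,
lab2,4,Oregon-R,F,6e-5,DR
lab1,1,Oregon-R,M,9e-8,DR
lab1,2,Oregon-R,M,0.001,
lab1,3,Oregon-R,M,3e-14,DR
lab1,4,Oregon-R,M,3e-10,DR
lab2,1,Oregon-R,M,0.7,
lab2,2,Oregon-R,M,5e-7,DR
lab2,3,Oregon-R,M,0.06,
lab2,4,Oregon-R,M,3e-6,DR
lab1,1,w1118,F,1,
lab1,2,w1118,F,0.1,
lab1,3,w1118,F,0.7,
lab1,4,w1118,F,0.5,
lab2,1,w1118,F,0.2,
lab2,2,w1118,F,2e-9,DR
lab2,3,w1118,F,0.008,
lab2,4,w1118,F,0.8,
lab1,1,w1118,M,5e-9,DR
lab1,2,w1118,M,0.03,
lab1,3,w1118,M,0.005,
lab1,4,w1118,M,3e-7,AL
lab2,1,w1118,M,0.5,
lab2,2,w1118,M,1e-7,DR
lab2,3,w1118,M,5e-4,DR
lab2,4,w1118,M,2e-4,DR
lab1,1,wDahomey,F,1,
lab1,2,wDahomey,F,0.1,
lab1,3,wDahomey,F,1e-4,DR
lab1,4,wDahomey,F,0.3,
lab2,1,wDahomey,F,1e-8,AL
lab2,2,wDahomey,F,0.04,
lab2,3,wDahomey,F,0.1,
lab2,4,wDahomey,F,0.6,
lab1,1,wDahomey,M,0.008,
lab1,2,wDahomey,M,0.01,
lab1,3,wDahomey,M,0.2,
lab1,4,wDahomey,M,0.3,
lab2,1,wDahomey,M,0.8,
lab2,2,wDahomey,M,0.6,
lab2,3,wDahomey,M,0.8,
lab2,4,wDahomey,M,0.06,
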