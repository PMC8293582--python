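selector_id,rank,feature,sign
filter_mi,1,Age,+
filter_mi,2,Sleep_Normal,-
filter_mi,3,BFType_Maternal,-
filter_mi,4,DiastolicPressure,-
filter_mi,5,MoSystolicPressure,+
filter_mi,6,MoNumberCigarettes,+
filter_mi,7,Birthheight,-
filter_mi,8,MoBMI,+
filter_mi,9,Birthweight,-
filter_mi,10,MoDiastolicPressure,-
svm_rfe,1,MoDietEducation,+
svm_rfe,2,MoRDType_LowSalt,+
svm_rfe,3,RDType_2000cal,+
svm_rfe,4,AdeDKnowledge,+
svm_rfe,5,MoPE_Inadequate,-
svm_rfe,6,DietCompliesAdvice,+
svm_rfe,7,MoRDType_Free,-
svm_rfe,8,MoPEHour,+
svm_rfe,9,DiastolicPressure,-
svm_rfe,10,SystolicPressure,+
ridge,1,Age,+
ridge,2,Sex,-
ridge,3,Tobacco_No,-
ridge,4,DietEducation,+
ridge,5,MoTobacco_Yes,+
ridge,6,BFType_Maternal,-
ridge,7,PE_Inadequate,+
ridge,8,MoDiabetes_No,-
ridge,9,PE_Adequate,-
ridge,10,MoDietEducation,+
lasso,1,Age,+
lasso,2,Sex,-
lasso,3,Tobacco_No,-
lasso,4,DietEducation,+
lasso,5,MoDietEducation,+
lasso,6,BFType_Maternal,-
lasso,7,Birthyear,-
lasso,8,MoNumberCigarettes,+
lasso,9,PE_Inadequate,+
lasso,10,DCExecution_No,+
random_forest,1,SystolicPressure,+
random_forest,2,MoDiastolicPressure,-
random_forest,3,MoSystolicPressure,-
random_forest,4,Sex,+
random_forest,5,Birthyear,-
random_forest,6,Tobacco_No,-
random_forest,7,MoExerciseAdvice,-
random_forest,8,MoAlcohol_No,-
random_forest,9,PE_Inadequate,+
random_forest,10,MoTobacco_Ex,+
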