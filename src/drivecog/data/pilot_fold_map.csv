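fold,role,group,subject_numbers
1,train,MCI,6 12 13 15 17 19
1,train,Healthy,3 5 8 9 14 16 18 21 22
1,test,MCI,1 10
1,test,Healthy,2 7 11 20
2,train,MCI,1 6 10 12 15 19
2,train,Healthy,2 5 7 8 9 11 16 18 20 21
2,test,MCI,13 17
2,test,Healthy,3 14 22
3,train,MCI,1 10 12 13 17 19
3,train,Healthy,2 3 5 7 9 11 14 18 20 22
3,test,MCI,6 15
3,test,Healthy,8 16 21
4,train,MCI,1 6 10 13 15 17
4,train,Healthy,2 3 7 8 11 14 16 20 21 22
4,test,MCI,12 19
4,test,Healthy,5 9 18
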